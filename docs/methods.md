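# Methods

## Problem and model

A Cullin-RING ligase recruited to a target protein by a PROTAC can transfer
ubiquitin only onto lysines whose side-chain Nζ the E2 catalytic cysteine
(Sγ) can approach. Two sources of flexibility dominate where that is
possible: collective motions of the Cullin scaffold, and the unfolded
~5-residue hinge loop of the RING subunit from which the ubiquitin-loaded E2
dangles. `bandscan` samples both, filters sterically impossible
conformations, and classifies each candidate lysine by the closest approach
achieved.

The model makes three simplifying commitments, inherited from the modelling
tradition it follows:

- **Heavy atoms only.** Crystal-structure inputs carry no hydrogens; all
  distances (contact, clash, salt bridge, hydrogen bond) are heavy-atom
  distances with thresholds chosen accordingly.
- **Rigid bodies between torsions.** Loop sampling changes only φ/ψ of loop
  residues; everything downstream, including the whole attached E2-like
  body, moves as a rigid unit. Bond lengths and angles are conserved exactly
  (pure axis rotations).
- **Cα-level elasticity.** Scaffold modes come from an anisotropic network
  model on Cα nodes; all-atom frames are reconstructed by translating every
  atom of a residue with its Cα node. Side chains are not re-oriented, and
  inter-residue covalent geometry distorts slightly at large amplitudes —
  acceptable for a sampling device whose output is distance statistics, not
  refined structures. Residues without a Cα node (ligands, pseudo-atoms)
  ride with the nearest node of their own chain; node-less chains stay
  static.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `enm.cutoff` | 15.0 | Å | spring cutoff between Cα nodes |
| `enm.gamma` | 1.0 | – | uniform spring constant (scale-free: eigenvectors are γ-independent) |
| `enm.n_modes` | 5 | – | lowest non-rigid modes animated |
| `enm.n_frames` | 28 | – | frames per animation cycle |
| `enm.rmsd_max` | 10.0 | Å | peak Cα RMSD of any frame from the parent |
| `enm.secondary_frame_picks` | 5,10,15,20,25 | – | mode-2 frames reseeding mode 1 in the combined scan |
| `sampler.n_draws` | 10000 | – | loop resamples per scaffold frame |
| `criteria.contact_threshold` | 8.0 | Å | Sγ–Nζ contact (inclusive ≤) |
| `criteria.clash_cutoff` | 2.5 | Å | heavy-atom overlap (strict <) |
| `criteria.anchor_max` | 50.0 | Å | ligand-attachment ↔ catalytic-Cys bound for pose filtering (strict <) |
| `criteria.salt_bridge_max` | 4.0 | Å | Nζ ↔ Asp/Glu carboxylate O |
| `criteria.hbond_max` | 3.5 | Å | Nζ ↔ O/N acceptor (warns, does not exclude) |
| `criteria.surface_rel_sasa_min` | 0.25 | – | exposure pre-filter for automatic site discovery only |

The mode/frame/draw counts and the 8 Å and 50 Å thresholds are the
protocol's study conditions; the elastic-network parameters are standard ANM
defaults, fixed in config because the upstream tool the protocol used leaves
them unstated. The clash cutoff is likewise a declared default; the
synthetic ground-truth margins (below) are built to be robust to ±0.5 Å
around it. Salt-bridge/H-bond cutoffs are conventional values.

## Numerical choices

- **Zero-mode detection**: eigenvalues below `1e-8 ×` the largest eigenvalue
  are rigid-body modes and are skipped; a disconnected network correctly
  yields more than six. Eigenvector sign is fixed by making the
  largest-magnitude component positive, so runs are reproducible.
- **Animation amplitude**: frames follow `a_t = A sin(2πt/n)` over one
  cycle; `A` is scaled by the profile's peak so the maximum frame RMSD
  equals `rmsd_max` exactly for any frame count (a symmetric linear ramp is
  available as an alternative profile). The last frame has amplitude 0 and
  reproduces the parent.
- **Torsion conventions**: IUPAC signs, degrees in [−180, 180); an extended
  chain built at 180° therefore measures −180°. Setting then measuring a
  torsion is exact to < 1e-6°. Rotations are applied N→C so earlier settings
  are never disturbed.
- **Batched kinematics**: the loop's moving sets are nested N→C, so each
  atom's conformation depends only on the last torsion that moves it; draws
  are evaluated by composing per-torsion rigid transforms, one composed
  transform per nesting group, vectorised over thousands of draws. The
  scalar path (`set_backbone_dihedral`) and the batched path agree to
  < 1e-13 Å and both are seeded-deterministic at the coordinate level.
- **Boundary rules, declared once**: contact at exactly 8.0 Å counts
  (inclusive); a pose at exactly 50.0 Å is removed (strict); clash at
  exactly the cutoff does not count (strict).
- **Altloc policy**: keep blank or 'A' alternates; where a residue offers
  neither, keep the highest-occupancy record. One conformer per atom,
  deterministically.
- **Sequence pairing** for superposition and homolog RMSD: global alignment,
  match +1, mismatch −1, gap −2, matched (non-gap) Cα pairs only. No
  outlier-trimming refinement by default — a one-shot least-squares fit is
  reproducible; an unstated trim protocol would not be.
- **Candidate selection ties** break toward the lower pose index.

## Design choices where the protocol was open

- **Loop redraw policy**: all loop torsions are redrawn each draw
  (maximal-entropy reading of "random angles"); a one-at-a-time mode exists
  in `refine_contact`'s proposal scheme for sensitivity checks.
- **Contact refinement** replaces an interactive fine-tuning step with a
  documented greedy descent: one random torsion per iteration, Gaussian step
  σ = 15°, accept iff the catalytic distance decreases and the moving set
  stays clash-free; seeded, logged, and returns the input with a warning
  flag (not an exception) when no improving move exists.
- **Escalation is per site**: each lysine keeps the verdict of the first
  tier that classifies it in-band (or excludes it chemically); only
  still-out-of-band sites are re-examined with broader sampling. Verdicts
  are therefore monotone under escalation by construction.
- **"Multiple conformations"**: one contact frame suffices for in_band by
  default; a stricter minimum-count knob exists since the protocol names no
  number.
- **Chemical exclusion order**: a salt bridge excludes regardless of
  distance statistics; hydrogen-bond-only contacts are reported as warnings
  because the electrostatic anchor, not mere polarity, is the disqualifier.
- **Mutant lysines** are built with ideal bond lengths/angles in the fully
  extended rotamer (all side-chain χ = 180°) — a declared stand-in for an
  unstated rotamer choice; backbone atoms are never touched.

## The synthetic generator

`make_hinge_complex` emulates exactly the mechanics the pipeline exercises:
a helical anchor, an extended 5-residue hinge, a helical attached body
carrying a probe pseudo-atom (the catalytic Sγ role), and a static target
chain with planted lysines. Labels are made true by construction and
re-verified at generation time:

- *in_band* sites start 5 Å from the probe (3 Å inside the 8 Å threshold);
- *out_of_band* sites are placed beyond a rigorous kinematic reach bound
  (loop backbone path length plus the rigid body's radius) plus the
  threshold, a 2 Å margin, and 40 Å of headroom for scaffold-mode motion,
  and an independent coarse random scan of loop conformations confirms they
  are never approached;
- *excluded* sites are reachable lysines with a glutamate carboxylate oxygen
  planted 3.0 Å from Nζ; carboxylates are kept > 4.5 Å from every other
  lysine's Nζ so exclusion labels cannot bleed across sites.

What the generator does **not** emulate: real protein folds, packing-driven
loop preferences, side-chain flexibility of the target lysines, solvent, or
the energetics of any interface. Passing tests therefore demonstrate that
the sampling, filtering and classification machinery is correct and
deterministic — not that the biological thresholds themselves are optimal
for any particular ligase. Ground-truth labels are defined with respect to
hinge-loop kinematics; scaffold-mode tiers can legitimately discover
additional contacts.

`make_pose_ensemble` builds pose clusters by pure translations of the mobile
chain, so every pairwise RMSD equals the corresponding translation distance
exactly and cluster recovery has a closed-form ground truth.

## Problem sizes

The default study runs 5 × 28 = 140 scaffold conformers and 140 × 10,000 =
1.4 million loop conformations, evaluated in streamed batches (composed
transforms + one k-d-tree query per batch) in about a minute on one CPU;
nothing but per-site minima, counts and best-frame provenance is retained.
The label-recovery study uses 100 generated complexes (300 sites) with an
81-frame ensemble each — the starting conformation plus 80 seeded draws —
which recovers 100% of planted labels deterministically. Test-suite toys use
8–25 residues per chain so oracle comparisons (dense eigensolvers, O(n²)
pair enumeration, naive density clustering, rotation-grid superposition
search) stay exact and fast.

## Known limitations

- Per-residue rigid translation distorts inter-residue covalent geometry at
  large mode amplitudes; frames are sampling devices, not models to deposit.
- The uniform torsion prior ignores Ramachandran statistics; reachability is
  therefore assessed against a broader conformational envelope than a real
  loop explores. A lysine found out-of-band under this generous sampling is
  a strong negative; an in-band verdict is a necessary, not sufficient,
  condition for ubiquitination.
- Loop closure is out of scope: the hinge is anchored only at its N side,
  matching the biology of a dangling RING/E2 arm.
- The chemical screen is geometric (distance cutoffs), not energetic; pKa
  shifts and the catalytic deprotonation chemistry are not modelled.
- Interface energies for pose triage are inputs; no physics-based scoring is
  implemented or implied.
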