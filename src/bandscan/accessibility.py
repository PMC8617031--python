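"""Lysine accessibility: clash filtering, catalytic distances, chemical
environment and surface-exposure screens, and band-region classification.

A lysine is a candidate ubiquitination site when, somewhere in the sampled
conformational ensemble, the E2 catalytic cysteine's Sgamma comes within the
contact threshold (default 8 A, inclusive) of the lysine's Nzeta in a
clash-free frame. A lysine whose ammonium group is tied up in a salt bridge
with a nearby carboxylate is excluded regardless of distance — the
electrostatic anchor both shields the charge and blocks the conformational
adjustment the transfer reaction needs. Hydrogen-bond-only contacts are
reported as warnings, not exclusions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
import biotite.structure as _bst

from .enm import ConformerEnsemble
from .structure import AtomSet, Structure, select

__all__ = ["ContactCriteria", "LysineSite", "AccessibilityResult",
           "BandRegionReport", "detect_clash", "catalytic_distance",
           "chemical_screen", "surface_exposure", "classify_band",
           "SiteAggregator"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactCriteria:
    """Distance thresholds of the accessibility analysis (Angstrom)."""

    contact_threshold: float = 8.0   # Sgamma-Nzeta contact (inclusive)
    clash_cutoff: float = 2.5        # heavy-atom steric overlap (strict <)
    anchor_max: float = 50.0         # ligand-attachment to catalytic-Cys bound
    salt_bridge_max: float = 4.0     # NZ to Asp/Glu carboxylate O
    hbond_max: float = 3.5           # NZ to O/N acceptor
    surface_rel_sasa_min: float = 0.25

    def __post_init__(self):
        values = (self.contact_threshold, self.clash_cutoff, self.anchor_max,
                  self.salt_bridge_max, self.hbond_max, self.surface_rel_sasa_min)
        if any(v <= 0 for v in values):
            raise ValueError("all criteria must be positive")
        if self.contact_threshold <= self.clash_cutoff:
            raise ValueError("contact_threshold must exceed clash_cutoff")


@dataclass
class LysineSite:
    """A (possibly mutant) lysine whose accessibility is evaluated."""

    chain_id: str
    res_seq: int
    label: str
    nz_index: int
    is_mutant: bool = False

    @classmethod
    def from_structure(cls, s: Structure, chain_id: str, res_seq: int,
                       label: str | None = None,
                       is_mutant: bool = False) -> "LysineSite":
        idx = s.residue_indices(chain_id, res_seq)
        if str(s.res_name[idx[0]]) != "LYS":
            raise ValueError(f"residue {chain_id}/{res_seq} is "
                             f"{s.res_name[idx[0]]}, not LYS")
        nz = s.find_atom(chain_id, res_seq, "NZ")
        return cls(chain_id, res_seq, label or f"K{res_seq}", nz,
                   is_mutant=is_mutant)


@dataclass
class AccessibilityResult:
    site: LysineSite
    min_distance: float
    n_contact_frames: int
    n_surviving_frames: int
    best_frame: dict | None
    exclusion: str  # "none" | "salt_bridge" | "buried"
    verdict: str    # "in_band" | "out_of_band" | "excluded"
    partners: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


@dataclass
class BandRegionReport:
    results: list[AccessibilityResult]
    metadata: dict = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        return [{"label": r.site.label,
                 "min_distance": r.min_distance,
                 "n_contact_frames": r.n_contact_frames,
                 "exclusion": r.exclusion,
                 "verdict": r.verdict} for r in self.results]


# ---------------------------------------------------------------------------
# Elementary measurements
# ---------------------------------------------------------------------------

def detect_clash(s: Structure, set_a: AtomSet, set_b: AtomSet, cutoff: float,
                 exclude_pairs: set[tuple[int, int]] | None = None) -> int:
    """Count heavy-atom pairs (a in A, b in B) closer than ``cutoff`` (strict).

    The sets must be disjoint. ``exclude_pairs`` removes covalently bonded and
    1-3 neighbour pairs across a seam from the count (given as global atom
    index pairs). Uses a k-d tree; equivalent to exhaustive pair enumeration.
    """
    if np.intersect1d(set_a.indices, set_b.indices).size:
        raise ValueError("clash sets must be disjoint")
    if len(set_a) == 0 or len(set_b) == 0:
        return 0
    tree = cKDTree(set_b.coord)
    pairs = tree.query_ball_point(set_a.coord, r=cutoff, p=2.0)
    count = 0
    for ia, neighbours in zip(set_a.indices, pairs):
        for jb in neighbours:
            d = np.linalg.norm(s.coord[ia] - set_b.coord[jb])
            if d < cutoff:
                gb = int(set_b.indices[jb])
                if exclude_pairs and ((int(ia), gb) in exclude_pairs
                                      or (gb, int(ia)) in exclude_pairs):
                    continue
                count += 1
    return count


def catalytic_distance(coord: np.ndarray, cys_sg: int, lys_nz: int) -> float:
    """Euclidean Sgamma-Nzeta distance in a coordinate frame (Angstrom)."""
    if max(cys_sg, lys_nz) >= len(coord) or min(cys_sg, lys_nz) < 0:
        raise KeyError("catalytic atom index outside frame")
    return float(np.linalg.norm(coord[cys_sg] - coord[lys_nz]))


_CARBOXYLATE_O = ("OD1", "OD2", "OE1", "OE2")


def chemical_screen(s: Structure, site: LysineSite,
                    criteria: ContactCriteria = ContactCriteria()
                    ) -> tuple[list[dict], bool]:
    """Salt-bridge / hydrogen-bond partners of a lysine's Nzeta.

    Salt-bridge partners are Asp/Glu side-chain carboxylate oxygens within
    ``salt_bridge_max``; hydrogen-bond partners are any other O/N acceptors
    within ``hbond_max``, excluding the lysine's own atoms. The site is
    excluded iff at least one salt-bridge partner exists.
    """
    nz = s.coord[site.nz_index]
    dists = np.linalg.norm(s.coord - nz, axis=1)
    own_residue = ((s.chain_id == site.chain_id) & (s.res_seq == site.res_seq)
                   & (s.icode == s.icode[site.nz_index]))
    partners = []
    salt = (np.isin(s.res_name, ["ASP", "GLU"]) & np.isin(s.name, _CARBOXYLATE_O)
            & (dists <= criteria.salt_bridge_max) & ~own_residue)
    for i in np.flatnonzero(salt):
        partners.append({"kind": "salt_bridge", "chain_id": str(s.chain_id[i]),
                         "res_seq": int(s.res_seq[i]),
                         "res_name": str(s.res_name[i]),
                         "atom": str(s.name[i]), "distance": float(dists[i])})
    hbond = (np.isin(s.element, ["O", "N"]) & (dists <= criteria.hbond_max)
             & ~own_residue & ~salt)
    for i in np.flatnonzero(hbond):
        partners.append({"kind": "hbond", "chain_id": str(s.chain_id[i]),
                         "res_seq": int(s.res_seq[i]),
                         "res_name": str(s.res_name[i]),
                         "atom": str(s.name[i]), "distance": float(dists[i])})
    excluded = any(p["kind"] == "salt_bridge" for p in partners)
    return partners, excluded


def surface_exposure(s: Structure, chain_id: str, res_seq: int,
                     point_number: int = 960, probe_radius: float = 1.4) -> float:
    """Relative solvent exposure of a residue.

    Shrake-Rupley SASA of the residue in context, divided by the SASA of the
    same residue type in an isolated extended Gly-X-Gly tripeptide. Values
    near 1 mean fully exposed; near 0, buried.
    """
    res_idx = s.residue_indices(chain_id, res_seq)
    arr = s.to_atom_array()
    sasa = _bst.sasa(arr, probe_radius=probe_radius, point_number=point_number,
                     vdw_radii="Single")
    context = float(np.nansum(sasa[res_idx]))

    res_name = str(s.res_name[res_idx[0]])
    reference = _gxg_reference_sasa(res_name, point_number, probe_radius)
    return context / reference


_ONE_LETTER = {"ALA": "A", "GLY": "G", "LYS": "K", "ASP": "D", "GLU": "E"}
_GXG_CACHE: dict[tuple, float] = {}


def _gxg_reference_sasa(res_name: str, point_number: int,
                        probe_radius: float) -> float:
    key = (res_name, point_number, probe_radius)
    if key not in _GXG_CACHE:
        from .synthetic import make_ideal_chain  # deferred; no import cycle
        letter = _ONE_LETTER.get(res_name)
        if letter is None:
            raise ValueError(f"no Gly-X-Gly reference for residue {res_name}; "
                             f"supported: {sorted(_ONE_LETTER)}")
        tri = make_ideal_chain(f"G{letter}G", "extended")
        arr = tri.to_atom_array()
        sasa = _bst.sasa(arr, probe_radius=probe_radius,
                         point_number=point_number, vdw_radii="Single")
        _GXG_CACHE[key] = float(np.nansum(sasa[tri.res_seq == 2]))
    return _GXG_CACHE[key]


# ---------------------------------------------------------------------------
# Ensemble classification
# ---------------------------------------------------------------------------

class SiteAggregator:
    """Streaming accumulator of per-site distance statistics over frames.

    Lets the pipeline evaluate millions of conformations without ever
    materialising them: feed clash-free frames (or batched distances) and read
    off minima, contact counts and best-frame provenance at the end.
    """

    def __init__(self, sites: list[LysineSite], criteria: ContactCriteria):
        self.sites = sites
        self.criteria = criteria
        self.min_distance = np.full(len(sites), np.inf)
        self.n_contact = np.zeros(len(sites), dtype=np.int64)
        self.best_frame: list[dict | None] = [None] * len(sites)
        self.n_frames = 0
        self.n_surviving = 0
        self.n_clashed = 0

    def add_frame(self, distances: np.ndarray, clashed: bool,
                  provenance: dict | None = None) -> None:
        self.n_frames += 1
        if clashed:
            self.n_clashed += 1
            return
        self.n_surviving += 1
        for k, d in enumerate(np.asarray(distances, dtype=float)):
            if d <= self.criteria.contact_threshold:
                self.n_contact[k] += 1
            if d < self.min_distance[k]:
                self.min_distance[k] = d
                self.best_frame[k] = provenance

    def add_batch(self, distances: np.ndarray, clashed: np.ndarray,
                  provenance: list[dict] | None = None,
                  provenance_fn=None) -> None:
        """Vectorised form: ``distances`` (B, n_sites), ``clashed`` (B,).

        ``provenance_fn(row)`` builds a provenance record lazily, only for
        rows that set a new per-site minimum (cheap at millions of draws).
        """
        distances = np.asarray(distances, dtype=float)
        clashed = np.asarray(clashed, dtype=bool)
        B = len(clashed)
        self.n_frames += B
        self.n_clashed += int(clashed.sum())
        ok = ~clashed
        self.n_surviving += int(ok.sum())
        if not np.any(ok):
            return
        d_ok = distances[ok]
        self.n_contact += (d_ok <= self.criteria.contact_threshold).sum(axis=0)
        mins = d_ok.min(axis=0)
        argmins = np.flatnonzero(ok)[d_ok.argmin(axis=0)]
        for k in range(len(self.sites)):
            if mins[k] < self.min_distance[k]:
                self.min_distance[k] = float(mins[k])
                row = int(argmins[k])
                if provenance is not None:
                    self.best_frame[k] = provenance[row]
                elif provenance_fn is not None:
                    self.best_frame[k] = provenance_fn(row)
                else:
                    self.best_frame[k] = None

    def finalise(self, structure: Structure,
                 metadata: dict | None = None) -> BandRegionReport:
        """Apply the chemical-environment screen and issue verdicts."""
        results = []
        for k, site in enumerate(self.sites):
            partners, chem_excluded = chemical_screen(structure, site, self.criteria)
            warnings_ = []
            if not chem_excluded and any(p["kind"] == "hbond" for p in partners):
                warnings_.append("hydrogen-bond contact at NZ (not excluding)")
            if chem_excluded:
                exclusion, verdict = "salt_bridge", "excluded"
            elif self.n_contact[k] >= 1:
                exclusion, verdict = "none", "in_band"
            else:
                exclusion, verdict = "none", "out_of_band"
            md = float(self.min_distance[k])
            results.append(AccessibilityResult(
                site=site, min_distance=md if np.isfinite(md) else float("inf"),
                n_contact_frames=int(self.n_contact[k]),
                n_surviving_frames=self.n_surviving,
                best_frame=self.best_frame[k], exclusion=exclusion,
                verdict=verdict, partners=partners, warnings=warnings_))
        if self.n_surviving == 0:
            logger.warning("all %d frames clashed; every site reported "
                           "out_of_band (or excluded)", self.n_frames)
        meta = {"n_frames": self.n_frames, "n_surviving": self.n_surviving,
                "n_clashed": self.n_clashed}
        if metadata:
            meta.update(metadata)
        return BandRegionReport(results=results, metadata=meta)


def classify_band(ensemble: ConformerEnsemble, sites: list[LysineSite],
                  cys_sg: int, criteria: ContactCriteria = ContactCriteria(),
                  moving: AtomSet | None = None,
                  poi: AtomSet | None = None) -> BandRegionReport:
    """Classify lysines as in-band / out-of-band / excluded over an ensemble.

    Frames where the moving set clashes with the target chain (strictly below
    ``clash_cutoff``) are discarded; surviving frames contribute Sgamma-Nzeta
    distances. A site is in-band iff it is not chemically excluded and at
    least one surviving frame is within the contact threshold (inclusive).
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    parent = ensemble.parent
    agg = SiteAggregator(sites, criteria)
    nz_idx = np.array([site.nz_index for site in sites], dtype=np.int64)
    for coord, info in zip(ensemble.frames, ensemble.provenance):
        clashed = False
        if moving is not None and poi is not None and len(moving) and len(poi):
            frame = parent.with_coord(coord)
            clashed = detect_clash(frame, AtomSet(frame, moving.indices),
                                   AtomSet(frame, poi.indices),
                                   criteria.clash_cutoff) > 0
        distances = np.linalg.norm(coord[nz_idx] - coord[cys_sg], axis=1)
        agg.add_frame(distances, clashed, info.to_dict())
    return agg.finalise(parent)
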