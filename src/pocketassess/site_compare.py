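"""Functional centers, site definitions, and site-to-site similarity.

Each site residue contributes one functional center: a representative
point for its functional chemistry (a single atom or the mean of a named
atom set) labelled with a chemistry class. Two sites are compared by
exhaustively scoring all permissible (same-class) center pairs with a
standardized Tanimoto similarity and aligning mutual most-similar pairs
greedily; the total over accepted pairs is the site score, more negative
meaning more similar than the random background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .microenvironment import BackgroundStats, FeatureVector, standardize
from .structure_io import Residue, ResidueSelector, StructureModel

__all__ = [
    "FunctionalCenter",
    "SiteDefinition",
    "PairScore",
    "SiteAlignment",
    "CENTER_MAP",
    "centers_from_residues",
    "extract_holo_site",
    "tanimoto",
    "pair_score",
    "align_sites",
    "greedy_match",
    "load_site_definition",
    "save_site_definition",
]

DEFAULT_CUTOFF = -0.5

# residue -> (atom names whose mean is the center, chemistry class)
CENTER_MAP: dict[str, tuple[tuple[str, ...], str]] = {
    "GLY": (("CA",), "backbone"),
    "ALA": (("CB",), "aliphatic"),
    "VAL": (("CG1", "CG2"), "aliphatic"),
    "LEU": (("CD1", "CD2"), "aliphatic"),
    "ILE": (("CD1",), "aliphatic"),
    "PRO": (("CG",), "aliphatic"),
    "MET": (("CE",), "aliphatic"),
    "SER": (("OG",), "hydroxyl"),
    "THR": (("OG1",), "hydroxyl"),
    "CYS": (("SG",), "thiol_thioether"),
    "ASP": (("OD1", "OD2"), "carboxylate"),
    "GLU": (("OE1", "OE2"), "carboxylate"),
    "ASN": (("OD1", "ND2"), "amide"),
    "GLN": (("OE1", "NE2"), "amide"),
    "LYS": (("NZ",), "amine"),
    "ARG": (("CZ",), "guanidinium"),
    "HIS": (("ND1", "NE2"), "imidazole"),
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), "aromatic"),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), "aromatic"),
    "TRP": (("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"), "aromatic"),
}
FALLBACK_CENTER = (("CA",), "backbone")


@dataclass
class FunctionalCenter:
    selector: ResidueSelector
    name3: str
    center: np.ndarray
    chem_class: str

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    @property
    def label(self) -> str:
        return f"{self.selector}:{self.name3}"


@dataclass
class SiteDefinition:
    target_id: str
    site_id: str
    category: str  # holo | apo | patch
    selectors: list[ResidueSelector]
    ligand: str | None = None

    def __post_init__(self) -> None:
        if self.category not in ("holo", "apo", "patch"):
            raise ValueError(f"unknown site category {self.category!r}")
        if not self.selectors:
            raise ValueError("a site needs at least one residue")
        if self.category == "holo" and not self.ligand:
            raise ValueError("holo sites must carry a ligand code")


@dataclass
class PairScore:
    label_a: str
    label_b: str
    chem_class: str
    raw_t: float
    score: float


@dataclass
class SiteAlignment:
    matches: list[PairScore] = field(default_factory=list)

    @property
    def total_score(self) -> float:
        return float(sum(m.score for m in self.matches))

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def centers_from_residues(structure: StructureModel,
                          residues: Sequence[Residue]) -> tuple[list[FunctionalCenter], list[Residue]]:
    """One functional center per residue via the fixed mapping table.

    Residues whose mapped atoms are all absent are skipped and returned
    in the miss report (second element).
    """
    centers: list[FunctionalCenter] = []
    missed: list[Residue] = []
    for res in residues:
        atom_names, chem_class = CENTER_MAP.get(res.name3, FALLBACK_CENTER)
        coords = [a.coords for name in atom_names if (a := res.atom(name)) is not None]
        if not coords:
            missed.append(res)
            continue
        centers.append(FunctionalCenter(
            selector=ResidueSelector(res.chain, res.seqnum, res.icode),
            name3=res.name3,
            center=np.mean(coords, axis=0),
            chem_class=chem_class,
        ))
    return centers, missed


def extract_holo_site(structure: StructureModel, ligand_code: str,
                      cutoff: float = 5.0) -> list[Residue]:
    """Polymer residues with any atom within ``cutoff`` of any ligand atom."""
    ligands = [r for r in structure.hetero if r.name3 == ligand_code.upper()]
    if not ligands:
        raise ValueError(f"ligand {ligand_code!r} not found among hetero residues")
    lig_coords = np.array([a.coords for r in ligands for a in r.atoms])
    hits: list[Residue] = []
    for res in structure.residues:
        coords = np.array([a.coords for a in res.atoms])
        if coords.size and cdist(coords, lig_coords).min() <= cutoff:
            hits.append(res)
    hits.sort(key=lambda r: (r.chain, r.seqnum, r.icode))
    return hits


def tanimoto(a: np.ndarray, b: np.ndarray, threshold: float = 1.0,
             variant: str = "binary") -> float:
    """Raw Tanimoto similarity of two standardized vectors, in [0, 1].

    binary: bit i set iff z_i > threshold; T = |A∩B| / |A∪B|.
    continuous: T = sum(min(p_a, p_b)) / sum(max(p_a, p_b)) over the
    positive parts p = max(z - threshold + 1, 0) -- a soft variant kept
    behind this switch for sensitivity analysis.
    An empty union scores 0 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if variant == "binary":
        bits_a = a > threshold
        bits_b = b > threshold
        union = np.logical_or(bits_a, bits_b).sum()
        if union == 0:
            return 0.0
        return float(np.logical_and(bits_a, bits_b).sum() / union)
    if variant == "continuous":
        pa = np.maximum(a - threshold + 1.0, 0.0)
        pb = np.maximum(b - threshold + 1.0, 0.0)
        denom = np.maximum(pa, pb).sum()
        if denom == 0:
            return 0.0
        return float(np.minimum(pa, pb).sum() / denom)
    raise ValueError(f"unknown tanimoto variant {variant!r}")


def pair_score(a: FeatureVector, b: FeatureVector, bg: BackgroundStats) -> PairScore:
    """Standardized similarity of a permissible (same-class) center pair.

    score = -(raw_t - mu) / sigma, so similarity above the random
    background is negative.
    """
    if not a.chem_class or a.chem_class != b.chem_class:
        raise ValueError(f"pair not permissible: {a.chem_class!r} vs {b.chem_class!r}")
    cls = a.chem_class
    if cls not in bg.pair_mean:
        raise ValueError(f"class {cls!r} has no calibrated background")
    raw = tanimoto(standardize(a, bg), standardize(b, bg),
                   threshold=bg.tanimoto_threshold, variant=bg.tanimoto_variant)
    score = -(raw - bg.pair_mean[cls]) / bg.pair_std[cls]
    return PairScore(label_a=a.center_label, label_b=b.center_label,
                     chem_class=cls, raw_t=raw, score=score)


def greedy_match(entries: Sequence[tuple[int, int, float]], cutoff: float
                 ) -> list[tuple[int, int, float]]:
    """Iterated mutual-best matching over a sparse score list.

    Repeatedly accepts the lowest-scoring pair among still-unmatched
    centers (ties broken by first-site then second-site index) while the
    score passes the cutoff. The globally lowest remaining pair is always
    a mutual best pair, so this realizes mutual-best-match alignment.
    """
    order = sorted(entries, key=lambda e: (e[2], e[0], e[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[tuple[int, int, float]] = []
    for ia, ib, s in order:
        if s > cutoff:
            break
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        out.append((ia, ib, s))
    return out


def align_sites(site_a: Sequence[FeatureVector], site_b: Sequence[FeatureVector],
                bg: BackgroundStats, cutoff: float = DEFAULT_CUTOFF) -> SiteAlignment:
    """Align two featurized sites by iterated mutual best match.

    Either site may be empty (empty alignment, total 0). Centers appear
    in at most one match; only pairs scoring at or below ``cutoff`` are
    accepted.
    """
    pairs: dict[tuple[int, int], PairScore] = {}
    entries: list[tuple[int, int, float]] = []
    for ia, va in enumerate(site_a):
        for ib, vb in enumerate(site_b):
            if not va.chem_class or va.chem_class != vb.chem_class:
                continue
            ps = pair_score(va, vb, bg)
            pairs[(ia, ib)] = ps
            entries.append((ia, ib, ps.score))
    matched = greedy_match(entries, cutoff)
    return SiteAlignment(matches=[pairs[(ia, ib)] for ia, ib, _ in matched])


# ---------------------------------------------------------------------------
# site-definition serialization (YAML)
# ---------------------------------------------------------------------------

def load_site_definition(path: str | Path) -> SiteDefinition:
    data = yaml.safe_load(Path(path).read_text())
    return SiteDefinition(
        target_id=data["target_id"],
        site_id=data.get("site_id", data["target_id"]),
        category=data["category"],
        selectors=[ResidueSelector.parse(str(s)) for s in data["residues"]],
        ligand=data.get("ligand"),
    )


def save_site_definition(site: SiteDefinition, path: str | Path) -> None:
    data = {
        "target_id": site.target_id,
        "site_id": site.site_id,
        "category": site.category,
        "residues": [str(s) for s in site.selectors],
    }
    if site.ligand:
        data["ligand"] = site.ligand
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
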