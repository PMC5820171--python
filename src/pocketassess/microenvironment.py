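"""Spherical microenvironment descriptors and background calibration.

A microenvironment is the spherical region of radius 7.5 Å around a
functional center, split into six concentric shells of 1.25 Å. For each
shell, 80 physicochemical property rules are aggregated over the heavy
polymer atoms whose center distance falls in that shell, giving a
480-dimensional descriptor (index = shell * 80 + property).

The 80 rules live in a packaged YAML manifest (``data/property_manifest.yaml``);
each rule names an extractor from the registry below and an aggregation
kind (``count``/``sum``/``mean``). All extractors are functions of atom and
residue identity plus scalar per-atom attributes only, so the descriptor
is invariant under rigid motion by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from . import chemistry as chem
from .structure_io import StructureModel

__all__ = [
    "ShellScheme",
    "PropertyRule",
    "PropertyManifest",
    "FeatureVector",
    "BackgroundStats",
    "AtomTable",
    "Featurizer",
    "assign_shell",
    "featurize",
    "build_background",
    "standardize",
    "load_default_manifest",
]

N_PROPERTIES = 80


@dataclass(frozen=True)
class ShellScheme:
    """Concentric half-open shells [k*w, (k+1)*w), k = 0..n_shells-1."""

    n_shells: int = 6
    shell_width: float = 1.25

    @property
    def radius(self) -> float:
        return self.n_shells * self.shell_width

    def __post_init__(self) -> None:
        if self.n_shells < 1 or self.shell_width <= 0:
            raise ValueError("invalid shell scheme")


def assign_shell(distance: float, scheme: ShellScheme = ShellScheme()) -> int | None:
    """Shell index for a distance, or None when outside the sphere."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    k = int(math.floor(distance / scheme.shell_width))
    return k if k < scheme.n_shells else None


@dataclass(frozen=True)
class PropertyRule:
    name: str
    kind: str  # count | sum | mean
    extractor: str

    def __post_init__(self) -> None:
        if self.kind not in ("count", "sum", "mean"):
            raise ValueError(f"unknown rule kind {self.kind!r}")


@dataclass(frozen=True)
class PropertyManifest:
    entries: tuple[PropertyRule, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != N_PROPERTIES:
            raise ValueError(f"manifest must have exactly {N_PROPERTIES} rules, "
                             f"got {len(self.entries)}")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("manifest rule names must be unique")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PropertyManifest":
        data = yaml.safe_load(Path(path).read_text())
        return cls(entries=tuple(PropertyRule(**e) for e in data["properties"]))


def load_default_manifest() -> PropertyManifest:
    ref = resources.files("pocketassess.data") / "property_manifest.yaml"
    with resources.as_file(ref) as path:
        return PropertyManifest.from_yaml(path)


@dataclass
class FeatureVector:
    """Shell-major descriptor (length n_shells * 80) with center metadata."""

    values: np.ndarray
    center: np.ndarray
    center_label: str = ""
    chem_class: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# extractor registry: name -> AtomTable -> per-atom value array
# ---------------------------------------------------------------------------

@dataclass
class AtomTable:
    """Columnar view over the heavy polymer atoms of one structure."""

    coords: np.ndarray          # (n, 3)
    element: np.ndarray         # (n,) str
    resname: np.ndarray         # (n,) str
    atomname: np.ndarray        # (n,) str
    bfactor: np.ndarray         # (n,)
    occupancy: np.ndarray       # (n,)
    ss_label: np.ndarray        # (n,) str: helix / extended / other

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def _ss_proxy_labels(structure: StructureModel) -> dict[tuple[str, int, str], str]:
    """Coarse secondary-structure proxy from backbone phi/psi bins.

    This replaces an external assignment tool: helix-like for phi/psi near
    (-60, -45), extended-like for beta-region dihedrals, 'other' otherwise
    or when a dihedral is undefined (chain termini, missing atoms).
    """
    labels: dict[tuple[str, int, str], str] = {}
    by_chain: dict[str, list] = {}
    for res in structure.residues:
        by_chain.setdefault(res.chain, []).append(res)
    for chain_residues in by_chain.values():
        for i, res in enumerate(chain_residues):
            label = "other"
            prev_res = chain_residues[i - 1] if i > 0 else None
            next_res = chain_residues[i + 1] if i + 1 < len(chain_residues) else None
            n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
            if (prev_res is not None and next_res is not None
                    and n is not None and ca is not None and c is not None):
                c_prev = prev_res.atom("C")
                n_next = next_res.atom("N")
                if c_prev is not None and n_next is not None:
                    phi = _dihedral(c_prev.coords, n.coords, ca.coords, c.coords)
                    psi = _dihedral(n.coords, ca.coords, c.coords, n_next.coords)
                    if -100.0 < phi < -30.0 and -80.0 < psi < -5.0:
                        label = "helix"
                    elif -180.0 <= phi < -45.0 and (psi > 90.0 or psi < -150.0):
                        label = "extended"
            labels[res.key] = label
    return labels


def build_atom_table(structure: StructureModel) -> AtomTable:
    """Heavy polymer atoms only; hydrogens and hetero residues are excluded."""
    ss = _ss_proxy_labels(structure)
    coords, element, resname, atomname, bfac, occ, label = [], [], [], [], [], [], []
    for res in structure.residues:
        res_label = ss.get(res.key, "other")
        for atom in res.atoms:
            if atom.is_hydrogen:
                continue
            coords.append(atom.coords)
            element.append(atom.element)
            resname.append(res.name3)
            atomname.append(atom.name)
            bfac.append(atom.bfactor)
            occ.append(atom.occupancy)
            label.append(res_label)
    if not coords:
        coords_arr = np.zeros((0, 3))
    else:
        coords_arr = np.asarray(coords, dtype=float)
    return AtomTable(
        coords=coords_arr,
        element=np.asarray(element, dtype=object),
        resname=np.asarray(resname, dtype=object),
        atomname=np.asarray(atomname, dtype=object),
        bfactor=np.asarray(bfac, dtype=float),
        occupancy=np.asarray(occ, dtype=float),
        ss_label=np.asarray(label, dtype=object),
    )


def _pair_mask(table: AtomTable, pairs: set[tuple[str, str]]) -> np.ndarray:
    mask = np.zeros(table.n, dtype=bool)
    for resn, atomn in pairs:
        if resn == "*":
            mask |= table.atomname == atomn
        else:
            mask |= (table.resname == resn) & (table.atomname == atomn)
    return mask


def _make_registry() -> dict[str, Callable[[AtomTable], np.ndarray]]:
    reg: dict[str, Callable[[AtomTable], np.ndarray]] = {}

    for aa in chem.AMINO_ACIDS:
        reg[f"residue_is:{aa}"] = (lambda t, aa=aa: (t.resname == aa).astype(float))
    for el in ("C", "N", "O", "S"):
        reg[f"element_is:{el}"] = (lambda t, el=el: (t.element == el).astype(float))

    reg["charge_class:positive"] = lambda t: np.isin(t.resname, sorted(chem.POSITIVE_RESIDUES)).astype(float)
    reg["charge_class:negative"] = lambda t: np.isin(t.resname, sorted(chem.NEGATIVE_RESIDUES)).astype(float)
    reg["charge_class:neutral"] = lambda t: (~np.isin(
        t.resname, sorted(chem.POSITIVE_RESIDUES | chem.NEGATIVE_RESIDUES))).astype(float)

    def formal_charge(t: AtomTable) -> np.ndarray:
        out = np.zeros(t.n)
        for (resn, atomn), q in chem.FORMAL_CHARGE_ATOMS.items():
            out[(t.resname == resn) & (t.atomname == atomn)] = q
        return out
    reg["formal_charge"] = formal_charge

    def kyte_doolittle_ca(t: AtomTable) -> np.ndarray:
        # residue hydropathy attributed to its CA so each residue in the
        # shell contributes exactly once
        out = np.zeros(t.n)
        at_ca = t.atomname == "CA"
        for aa, kd in chem.KYTE_DOOLITTLE.items():
            out[at_ca & (t.resname == aa)] = kd
        return out
    reg["kyte_doolittle_ca"] = kyte_doolittle_ca

    reg["hbond_donor"] = lambda t: _pair_mask(t, chem.HBOND_DONORS).astype(float)
    reg["hbond_acceptor"] = lambda t: _pair_mask(t, chem.HBOND_ACCEPTORS).astype(float)

    def aromatic_ring(t: AtomTable) -> np.ndarray:
        mask = np.zeros(t.n, dtype=bool)
        for resn, atoms in chem.AROMATIC_RING_ATOMS.items():
            mask |= (t.resname == resn) & np.isin(t.atomname, sorted(atoms))
        return mask.astype(float)
    reg["aromatic_ring"] = aromatic_ring

    reg["backbone"] = lambda t: np.isin(t.atomname, sorted(chem.BACKBONE_ATOMS)).astype(float)
    reg["sidechain"] = lambda t: (~np.isin(t.atomname, sorted(chem.BACKBONE_ATOMS))).astype(float)
    reg["bfactor"] = lambda t: t.bfactor.copy()
    reg["occupancy"] = lambda t: t.occupancy.copy()

    for cls in chem.RESIDUE_CLASSES:
        reg[f"residue_class:{cls}"] = (
            lambda t, cls=cls: np.isin(t.resname, sorted(chem.RESIDUE_CLASSES[cls])).astype(float))
    for grp in chem.FUNCTIONAL_GROUP_ATOMS:
        reg[f"functional_group:{grp}"] = (
            lambda t, grp=grp: _pair_mask(t, chem.FUNCTIONAL_GROUP_ATOMS[grp]).astype(float))
    for lab in ("helix", "extended", "other"):
        reg[f"ss_ca:{lab}"] = (
            lambda t, lab=lab: ((t.atomname == "CA") & (t.ss_label == lab)).astype(float))

    def atom_is(t: AtomTable, name: str) -> np.ndarray:
        return (t.atomname == name).astype(float)
    for name in ("N", "CA", "C", "O", "CB", "CG", "CG1", "CG2", "CD", "CD1", "CD2",
                 "CE", "CE1", "CE2", "CZ", "OG", "OG1", "OH", "OD1", "OD2", "OE1",
                 "OE2", "ND1", "ND2", "NE", "NE1", "NE2"):
        reg[f"atom_is:{name}"] = (lambda t, name=name: atom_is(t, name))

    return reg


EXTRACTOR_REGISTRY = _make_registry()


class Featurizer:
    """Reusable featurization engine.

    Precomputes the per-atom contribution matrix once per structure so
    that featurizing many centers on the same structure is a couple of
    matrix operations.
    """

    def __init__(self, manifest: PropertyManifest | None = None,
                 scheme: ShellScheme | None = None) -> None:
        self.manifest = manifest or load_default_manifest()
        self.scheme = scheme or ShellScheme()
        for rule in self.manifest.entries:
            if rule.extractor not in EXTRACTOR_REGISTRY:
                raise KeyError(f"unknown extractor {rule.extractor!r} in rule {rule.name!r}")
        self._mean_mask = np.array([e.kind == "mean" for e in self.manifest.entries])

    def annotate(self, structure: StructureModel) -> tuple[AtomTable, np.ndarray]:
        table = build_atom_table(structure)
        contrib = np.zeros((table.n, N_PROPERTIES))
        if table.n:
            for j, rule in enumerate(self.manifest.entries):
                contrib[:, j] = EXTRACTOR_REGISTRY[rule.extractor](table)
        return table, contrib

    def featurize_center(self, annotated: tuple[AtomTable, np.ndarray],
                         center: np.ndarray, label: str = "",
                         chem_class: str = "") -> FeatureVector:
        table, contrib = annotated
        scheme = self.scheme
        n_shells = scheme.n_shells
        values = np.zeros((n_shells, N_PROPERTIES))
        if table.n:
            d = np.linalg.norm(table.coords - np.asarray(center, dtype=float), axis=1)
            shell = np.floor(d / scheme.shell_width).astype(int)
            inside = shell < n_shells
            onehot = np.zeros((n_shells, table.n))
            onehot[shell[inside], np.nonzero(inside)[0]] = 1.0
            values = onehot @ contrib
            counts = onehot.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(counts[:, None] > 0,
                                 values / np.maximum(counts[:, None], 1), 0.0)
            values[:, self._mean_mask] = means[:, self._mean_mask]
        return FeatureVector(values=values.reshape(-1), center=np.asarray(center, float),
                             center_label=label, chem_class=chem_class)


def featurize(structure: StructureModel, center, manifest: PropertyManifest | None = None,
              scheme: ShellScheme | None = None, label: str = "",
              chem_class: str = "") -> FeatureVector:
    """One-shot descriptor for a single center (see :class:`Featurizer`)."""
    fz = Featurizer(manifest, scheme)
    return fz.featurize_center(fz.annotate(structure), center, label, chem_class)


# ---------------------------------------------------------------------------
# background statistics
# ---------------------------------------------------------------------------

@dataclass
class BackgroundStats:
    """Standardization constants plus raw-similarity background per class.

    ``dim_std`` entries equal to zero mark unretained dimensions; their
    standardized value is defined as 0. ``pair_mean``/``pair_std`` hold the
    mean and population std of the raw Tanimoto similarity of randomly
    sampled same-class center pairs, keyed by chemistry class.
    """

    dim_mean: np.ndarray
    dim_std: np.ndarray
    retained: np.ndarray
    pair_mean: dict[str, float]
    pair_std: dict[str, float]
    pool_size: int
    seed: int
    tanimoto_threshold: float = 1.0
    tanimoto_variant: str = "binary"

    @property
    def n_dim(self) -> int:
        return self.dim_mean.size


def standardize(vector: FeatureVector | np.ndarray, bg: BackgroundStats) -> np.ndarray:
    """Per-dimension z-transform; unretained (zero-variance) dims map to 0."""
    v = vector.values if isinstance(vector, FeatureVector) else np.asarray(vector, float)
    if v.size != bg.n_dim:
        raise ValueError(f"dimension mismatch: vector {v.size}, background {bg.n_dim}")
    out = np.zeros_like(v)
    np.divide(v - bg.dim_mean, bg.dim_std, out=out, where=bg.retained)
    return out


def build_background(vectors: Sequence[FeatureVector], centers: Sequence | None = None,
                     n_pairs: int = 200, seed: int = 0,
                     tanimoto_threshold: float = 1.0,
                     tanimoto_variant: str = "binary") -> BackgroundStats:
    """Calibrate standardization and raw-similarity background from a pool.

    ``centers`` defaults to the vectors themselves (their ``chem_class``
    labels group the pool for pair sampling). Deterministic for a given
    seed; raises when no dimension has variance or a represented class has
    fewer than two centers.
    """
    from .site_compare import tanimoto  # local import to avoid a cycle

    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors to build a background")
    mat = np.stack([np.asarray(v.values, float) for v in vectors])
    dim_mean = mat.mean(axis=0)
    dim_std = mat.std(axis=0)  # population std
    retained = dim_std > 0
    if not retained.any():
        raise ValueError("no descriptor dimension has nonzero variance in the pool")

    classes = [getattr(c, "chem_class", "") for c in (centers if centers is not None else vectors)]
    if len(classes) != len(vectors):
        raise ValueError("centers and vectors must align")
    bg = BackgroundStats(dim_mean=dim_mean, dim_std=dim_std, retained=retained,
                         pair_mean={}, pair_std={}, pool_size=len(vectors), seed=seed,
                         tanimoto_threshold=tanimoto_threshold,
                         tanimoto_variant=tanimoto_variant)
    std_vecs = [standardize(v, bg) for v in vectors]

    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, cls in enumerate(classes):
        by_class.setdefault(cls, []).append(i)
    for cls in sorted(by_class):
        if cls == "":  # unlabeled pools calibrate dimension stats only
            continue
        idx = by_class[cls]
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 centers in the pool")
        scores = np.empty(n_pairs)
        for k in range(n_pairs):
            i, j = rng.choice(len(idx), size=2, replace=False)
            scores[k] = tanimoto(std_vecs[idx[i]], std_vecs[idx[j]],
                                 threshold=tanimoto_threshold, variant=tanimoto_variant)
        mu = float(scores.mean())
        sigma = float(scores.std())
        if sigma == 0.0:
            raise ValueError(f"raw-similarity background for class {cls!r} has zero variance")
        bg.pair_mean[cls] = mu
        bg.pair_std[cls] = sigma
    return bg
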