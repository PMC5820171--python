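"""Synthetic reference structures, noise-graded model ensembles, and the
packaged site-inventory fixture.

The generator builds a solenoid-like backbone (consecutive CA-CA distance
3.8 Å) whose axis region forms a concave pocket; side-chain proxy atoms
point inward, so a small ligand placed on the axis sits 2.5-4.5 Å from the
protein. "Predicted" models are the reference plus independently
controllable global and site-local i.i.d. Gaussian coordinate noise --
statistically transparent degradation rather than physically realistic
decoys, which is all the downstream analysis needs.
"""

from __future__ import annotations

import copy
import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .site_compare import CENTER_MAP, SiteDefinition
from .structure_io import Atom, Residue, ResidueSelector, StructureModel

__all__ = [
    "EnsembleConfig",
    "EnsembleResult",
    "SiteTableFixture",
    "generate_reference",
    "perturb_model",
    "generate_ensemble",
    "load_site_table",
]

AA_CHOICES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

SITE_TABLE_SHA256 = "c38f40137b8da4eeb68fb556bd1371ce539a2154dac50340d441ff93aa12fefd"


@dataclass
class EnsembleConfig:
    n_residues: int = 60
    n_models: int = 50
    global_sigma: float = 1.0
    local_sigma: float = 1.0
    site_size: int = 8
    anti_coupled_fraction: float = 0.0
    with_ligand: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.global_sigma < 0 or self.local_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        if self.n_models < 3:
            raise ValueError("need at least 3 models")
        if self.site_size < 3:
            raise ValueError("site_size must be >= 3")


@dataclass
class EnsembleResult:
    reference: StructureModel
    site: SiteDefinition
    models: list[StructureModel]
    manifest: pd.DataFrame


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _sidechain_atoms(name3: str, ca: np.ndarray, inward: np.ndarray,
                     tangent: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Proxy side-chain atoms consistent with the center-mapping table."""
    u = _unit(np.cross(tangent, inward))
    atoms: list[tuple[str, np.ndarray]] = []
    if name3 != "GLY":
        atoms.append(("CB", ca + 1.5 * inward))
    mapped, _ = CENTER_MAP.get(name3, (("CA",), "backbone"))
    mapped = [a for a in mapped if a not in ("CA", "CB")]
    if len(mapped) == 1:
        atoms.append((mapped[0], ca + 2.6 * inward))
    elif len(mapped) == 2:
        atoms.append((mapped[0], ca + 2.6 * inward + 0.8 * u))
        atoms.append((mapped[1], ca + 2.6 * inward - 0.8 * u))
    elif len(mapped) > 2:  # aromatic rings: circle around the ring centroid
        centroid = ca + 2.6 * inward
        for k, name in enumerate(mapped):
            ang = 2.0 * math.pi * k / len(mapped)
            atoms.append((name, centroid + 1.2 * (math.cos(ang) * u + math.sin(ang) * tangent)))
    return atoms


def generate_reference(n_residues: int, with_ligand: bool = False, seed: int = 0,
                       site_size: int = 8) -> tuple[StructureModel, SiteDefinition]:
    """Deterministic solenoid protein with a concave axial pocket.

    The site lists the ``site_size`` residues whose CA is closest to the
    pocket midpoint; with a ligand the site is holo (ligand code LIG)
    and the hetero group is placed 2.5-4.5 Å from the protein.
    """
    if n_residues < 20:
        raise ValueError("need at least 20 residues")
    rng = np.random.default_rng(seed)

    alpha = 2.0 * math.pi / 13.0     # 13 residues per turn
    dz = 1.0
    radius = math.sqrt(3.8 ** 2 - dz ** 2) / (2.0 * math.sin(alpha / 2.0))
    idx = np.arange(n_residues)
    ca = np.stack([radius * np.cos(idx * alpha),
                   radius * np.sin(idx * alpha),
                   idx * dz], axis=1)
    ca = ca + rng.normal(0.0, 0.02, size=ca.shape)  # break exact symmetry

    # sequence depends only on length: changing the seed must change
    # coordinates but not atom counts or identities
    sequence = np.random.default_rng(1337 + n_residues).choice(AA_CHOICES, size=n_residues)
    residues: list[Residue] = []
    serial = 0

    def mk_atom(name: str, coords: np.ndarray) -> Atom:
        nonlocal serial
        serial += 1
        element = name.lstrip("0123456789")[0]
        return Atom(serial=serial, name=name, element=element, coords=coords,
                    occupancy=1.0, bfactor=float(10.0 + rng.normal(0, 2)))

    for i in range(n_residues):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - (ca[i + 1] - ca[i])
        next_ca = ca[i + 1] if i + 1 < n_residues else ca[i] + (ca[i] - ca[i - 1])
        tangent = _unit(next_ca - prev_ca)
        inward = _unit(np.array([-ca[i, 0], -ca[i, 1], 0.0]))
        u = _unit(np.cross(tangent, inward))
        res = Residue(chain="A", seqnum=i + 1, icode="", name3=str(sequence[i]))
        res.atoms.append(mk_atom("N", ca[i] - 1.2 * tangent + 0.5 * u))
        res.atoms.append(mk_atom("CA", ca[i]))
        res.atoms.append(mk_atom("C", ca[i] + 1.2 * tangent + 0.5 * u))
        res.atoms.append(mk_atom("O", ca[i] + 1.2 * tangent + 0.5 * u + 1.23 * np.cross(tangent, u)))
        for name, coords in _sidechain_atoms(res.name3, ca[i], inward, tangent):
            res.atoms.append(mk_atom(name, coords))
        residues.append(res)

    z_mid = float(ca[:, 2].mean())
    pocket = np.array([0.0, 0.0, z_mid])
    order = np.argsort(np.linalg.norm(ca - pocket, axis=1))
    site_idx = sorted(order[:site_size].tolist())
    selectors = [ResidueSelector("A", i + 1) for i in site_idx]

    structure = StructureModel(target_id=f"SYN{seed:04d}", source_id="experimental",
                               model_index=0, residues=residues)

    ligand_code = None
    if with_ligand:
        offsets = 0.7 * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3)
        lig_center = pocket.copy()
        protein_xyz = np.array([a.coords for r in residues for a in r.atoms])
        for _ in range(40):  # radial walk until the contact distance is in range
            lig_xyz = lig_center + offsets
            dmat = np.linalg.norm(protein_xyz[:, None, :] - lig_xyz[None, :, :], axis=2)
            dmin = float(dmat.min())
            if 2.5 <= dmin <= 4.5:
                break
            nearest = protein_xyz[np.unravel_index(dmat.argmin(), dmat.shape)[0]]
            step = _unit(nearest - lig_center)
            lig_center = lig_center + (0.3 if dmin > 4.5 else -0.3) * step
        else:
            raise RuntimeError("could not place ligand within contact range")
        lig = Residue(chain="A", seqnum=900, icode="", name3="LIG")
        for k, xyz in enumerate(lig_center + offsets):
            lig.atoms.append(mk_atom(f"C{k + 1}", xyz))
        structure.hetero.append(lig)
        ligand_code = "LIG"

    site = SiteDefinition(
        target_id=structure.target_id,
        site_id=f"{structure.target_id}-S1",
        category="holo" if with_ligand else "apo",
        selectors=selectors,
        ligand=ligand_code,
    )
    return structure, site


def _copy_structure(structure: StructureModel) -> StructureModel:
    return copy.deepcopy(structure)


def perturb_model(reference: StructureModel, global_sigma: float,
                  local_sigma: float, site: SiteDefinition | None, seed: int,
                  nonsite_only: bool = False) -> StructureModel:
    """Noisy copy of the reference (identity and numbering preserved).

    i.i.d. zero-mean Gaussian noise of std ``global_sigma`` on every
    coordinate, plus independent noise of std ``local_sigma`` on the
    atoms of site residues. ``nonsite_only`` restricts the global term to
    non-site residues (used to inject good-local/bad-global models).
    """
    if global_sigma < 0 or local_sigma < 0:
        raise ValueError("sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    model = _copy_structure(reference)
    site_keys = {(s.chain, s.seqnum, s.icode or "") for s in site.selectors} if site else set()
    for res in model.residues + model.hetero:
        in_site = res.key in site_keys
        for atom in res.atoms:
            if global_sigma > 0 and not (nonsite_only and in_site):
                atom.coords = atom.coords + rng.normal(0.0, global_sigma, size=3)
            if local_sigma > 0 and in_site:
                atom.coords = atom.coords + rng.normal(0.0, local_sigma, size=3)
    return model


def generate_ensemble(config: EnsembleConfig) -> EnsembleResult:
    """Noise-graded ensemble grouped into 5-model 'servers'.

    Within each server the noise grows with model index, so model 1 is
    the server's best (emulating predictor self-ranking). A fraction of
    non-model-1 slots can be replaced by anti-coupled models: site kept
    exact, everything else strongly perturbed.
    """
    reference, site = generate_reference(config.n_residues, config.with_ligand,
                                         seed=config.seed, site_size=config.site_size)
    n_servers = math.ceil(config.n_models / 5)
    master = np.random.default_rng(config.seed + 1)

    slots = []  # (server index, model index)
    for s in range(n_servers):
        for j in range(1, 6):
            if len(slots) < config.n_models:
                slots.append((s, j))
    n_anti = int(round(config.anti_coupled_fraction * config.n_models))
    anti_slots = set()
    for s, j in reversed(slots):  # inject into trailing non-model-1 slots
        if len(anti_slots) >= n_anti:
            break
        if j != 1:
            anti_slots.add((s, j))

    server_base = np.linspace(0.2, 1.0, n_servers)
    models: list[StructureModel] = []
    rows = []
    for s, j in slots:
        server_id = f"S{s + 1:02d}"
        seed = int(master.integers(2 ** 31))
        anti = (s, j) in anti_slots
        if anti:
            gs = max(4.0, 4.0 * config.global_sigma)
            ls = 0.0
            model = perturb_model(reference, gs, 0.0, site, seed, nonsite_only=True)
        else:
            grade = server_base[s] * (1.0 + 0.35 * (j - 1))
            gs = config.global_sigma * grade
            ls = config.local_sigma * grade
            model = perturb_model(reference, gs, ls, site, seed)
        model.source_id = server_id
        model.model_index = j
        models.append(model)
        site_sigma = 0.0 if anti else math.hypot(gs, ls)
        rows.append({"model_id": f"{server_id}#{j}", "server": server_id,
                     "model_index": j, "global_sigma": gs, "local_sigma": ls,
                     "anti_coupled": anti, "site_sigma": site_sigma})
    manifest = pd.DataFrame(rows)
    return EnsembleResult(reference=reference, site=site, models=models,
                          manifest=manifest)


# ---------------------------------------------------------------------------
# packaged site-inventory fixture
# ---------------------------------------------------------------------------

@dataclass
class SiteTableFixture:
    table: pd.DataFrame = field(repr=False)

    @property
    def n_sites(self) -> int:
        return len(self.table)

    def count(self, category: str) -> int:
        return int((self.table["category"] == category).sum())


def load_site_table() -> SiteTableFixture:
    """Load the packaged 28-row site inventory (9 holo / 9 apo / 10 patch).

    The file is checksummed; corruption raises before any invariant check.
    """
    ref = resources.files("pocketassess.data") / "site_table.tsv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != SITE_TABLE_SHA256:
        raise ValueError(f"site table fixture corrupt: sha256 {digest}")
    from io import BytesIO
    table = pd.read_csv(BytesIO(raw), sep="\t", dtype={"n_centers": str})
    if len(table) != 28:
        raise ValueError(f"expected 28 sites, found {len(table)}")
    counts = table["category"].value_counts().to_dict()
    if (counts.get("holo"), counts.get("apo"), counts.get("patch")) != (9, 9, 10):
        raise ValueError(f"unexpected category counts: {counts}")
    return SiteTableFixture(table=table)
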