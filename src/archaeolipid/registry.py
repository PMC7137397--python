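"""Catalogue of archaeal core-lipid structures.

The registry is the shared vocabulary of the whole pipeline: every
chromatogram channel, every composition column and every statistic is keyed
by the short ids defined here (``DGD``, ``GDGT-0`` … ``GDGT-4``, ``GMGT-0/1``,
``GTGT-0/1`` plus the rarer diether skeletons).  Masses are the nominal
protonated-molecule ([M+H]+) values observed under APCI; within a skeleton
each additional cyclopentane ring removes two hydrogens and hence 2.0 Da.

Note that at unit mass resolution several structures are isobaric
(GTGT-0/GDGT-0 at m/z 1302.5; GTGT-1/GDGT-1/GMGT-0 at 1300.5;
GDGT-2/GMGT-1 at 1298.5) and are told apart only by retention time, with
the elution order DGD < GTGT < GDGT < GMGT.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "LipidSpecies",
    "DIETHER_SKELETONS",
    "TETRAETHER_SKELETONS",
    "default_registry",
    "isobaric_groups",
    "registry_to_tsv",
    "registry_from_tsv",
]

#: skeletons whose core is two independent alkyl chains (bilayer-forming)
DIETHER_SKELETONS = frozenset({"DGD", "macrocyclic-DGD", "C20C25-diether", "C25C25-diether"})
#: membrane-spanning skeletons (monolayer-forming)
TETRAETHER_SKELETONS = frozenset({"GDGT", "GMGT", "GTGT"})

_MAX_RINGS = {"GDGT": 4, "GMGT": 1, "GTGT": 1}

#: mass removed per cyclopentane ring (loss of two hydrogens), Da
RING_MASS_STEP = 2.0


@dataclass(frozen=True)
class LipidSpecies:
    """One core-lipid structure.

    Parameters
    ----------
    id : str
        Short label, e.g. ``"GDGT-2"``.
    skeleton : str
        One of the diether or tetraether skeleton names.
    n_rings : int
        Number of cyclopentane rings (0 for all diethers).
    mz_proton : float
        Nominal [M+H]+ mass-to-charge, Da.
    rt_center : float
        Nominal retention time, min.  Configuration, not chemistry: any
        values are acceptable provided the class elution order
        DGD < GTGT < GDGT < GMGT is preserved.
    response_factor : float
        Molar detector response relative to the tetraether class
        (diethers respond ~10x weaker under APCI, hence 0.1).
    """

    id: str
    skeleton: str
    n_rings: int
    mz_proton: float
    rt_center: float
    response_factor: float

    def __post_init__(self) -> None:
        if self.skeleton not in DIETHER_SKELETONS | TETRAETHER_SKELETONS:
            raise ValueError(f"unknown skeleton {self.skeleton!r}")
        max_rings = _MAX_RINGS.get(self.skeleton, 0)
        if not 0 <= self.n_rings <= max_rings:
            raise ValueError(
                f"{self.id}: n_rings={self.n_rings} outside [0, {max_rings}] for {self.skeleton}"
            )
        if self.mz_proton <= 0:
            raise ValueError(f"{self.id}: mz_proton must be positive")
        if self.response_factor <= 0:
            raise ValueError(f"{self.id}: response_factor must be positive")

    @property
    def lipid_class(self) -> str:
        """``"diether"`` or ``"tetraether"``, determined by the skeleton."""
        return "diether" if self.skeleton in DIETHER_SKELETONS else "tetraether"


def default_registry() -> list[LipidSpecies]:
    """Return the 13-entry default catalogue.

    Masses are anchored to the observed [M+H]+ values (DGD 653.5,
    GDGT-0 1302.5, GMGT-0 1300.5, GTGT-0 1302.5) with ring variants at
    -2 Da per ring.  Retention times are nominal minutes chosen to
    respect the observed elution order; they carry no chemical meaning.
    """
    d, t = 0.1, 1.0  # response factors: diether, tetraether

    def rings(base_id: str, skeleton: str, base_mz: float, base_rt: float,
              rt_step: float) -> list[LipidSpecies]:
        return [
            LipidSpecies(f"{base_id}-{n}", skeleton, n,
                         base_mz - RING_MASS_STEP * n, base_rt + rt_step * n, t)
            for n in range(_MAX_RINGS[skeleton] + 1)
        ]

    return [
        LipidSpecies("DGD", "DGD", 0, 653.5, 5.0, d),
        LipidSpecies("macrocyclic-DGD", "macrocyclic-DGD", 0, 651.5, 6.0, d),
        LipidSpecies("C20C25-diether", "C20C25-diether", 0, 723.5, 7.0, d),
        LipidSpecies("C25C25-diether", "C25C25-diether", 0, 793.5, 8.0, d),
        *rings("GTGT", "GTGT", 1302.5, 12.0, 1.0),
        *rings("GDGT", "GDGT", 1302.5, 18.0, 1.5),
        *rings("GMGT", "GMGT", 1300.5, 30.0, 1.0),
    ]


def isobaric_groups(registry: Iterable[LipidSpecies], mz_tol: float = 0.5) -> list[list[str]]:
    """Group species indistinguishable by m/z alone.

    Returns every maximal set of >= 2 species whose [M+H]+ values lie
    within ``mz_tol`` of each other, members ordered by retention time.
    Deterministic: groups are sorted by their (common) m/z.
    """
    species = sorted(registry, key=lambda s: (s.mz_proton, s.rt_center, s.id))
    if not species:
        raise ValueError("registry is empty")
    groups: list[list[LipidSpecies]] = []
    current = [species[0]]
    for sp in species[1:]:
        if sp.mz_proton - current[0].mz_proton <= mz_tol:
            current.append(sp)
        else:
            groups.append(current)
            current = [sp]
    groups.append(current)
    return [
        [s.id for s in sorted(g, key=lambda s: s.rt_center)]
        for g in groups
        if len(g) >= 2
    ]


_TSV_HEADER = "id\tskeleton\tclass\tn_rings\tmz\trt\trf"


def registry_to_tsv(registry: Iterable[LipidSpecies], path: str | Path) -> None:
    """Serialize a registry to TSV (columns id, skeleton, class, n_rings, mz, rt, rf)."""
    lines = [_TSV_HEADER]
    for s in registry:
        lines.append(
            f"{s.id}\t{s.skeleton}\t{s.lipid_class}\t{s.n_rings}"
            f"\t{s.mz_proton}\t{s.rt_center}\t{s.response_factor}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def registry_from_tsv(path: str | Path) -> list[LipidSpecies]:
    """Read a registry written by :func:`registry_to_tsv`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != _TSV_HEADER:
        raise ValueError(f"{path}: not a registry TSV (bad header)")
    out = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"{path}: line {i}: expected 7 fields, got {len(parts)}")
        out.append(
            LipidSpecies(parts[0], parts[1], int(parts[3]),
                         float(parts[4]), float(parts[5]), float(parts[6]))
        )
    ids = [s.id for s in out]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate lipid ids")
    return out
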