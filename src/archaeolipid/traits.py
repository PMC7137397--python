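"""Taxonomy-level inference of lipid-synthesis ability and membranes.

Lipid surveys are patchy: many species were screened for only one lipid
class, and extraction protocols routinely miss tetraethers.  The parsimony
rule implemented here fills those gaps: if one or more species of a genus
has an *observed* ability to synthesize a lipid class, every co-genus
species with *unknown* status is *assumed* to share it; a documented
absence is never overwritten.  The same rule can be applied at a coarser
rank (order) where genus-level evidence is thin.

Membrane categories follow the three-way split used for domain-wide
surveys: diether_only (bilayer only), mixed (both classes), and
tetraether_dominant (diether present only in trace amounts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .quantify import ND, CompositionProfile
from .stats import _skeleton_class

__all__ = [
    "OBSERVED", "ASSUMED", "UNKNOWN", "ABSENT",
    "TaxonRecord",
    "propagate_genus_rule", "categorize_membrane", "category_medians",
    "ancestral_composition", "count_by_filter", "round_to_ten",
]

OBSERVED = "observed"
ASSUMED = "assumed"
UNKNOWN = "unknown"
ABSENT = "absent"
_ABILITIES = {OBSERVED, ASSUMED, UNKNOWN, ABSENT}

DIETHER_ONLY = "diether_only"
MIXED = "mixed"
TETRAETHER_DOMINANT = "tetraether_dominant"
UNSET = "unset"


@dataclass(frozen=True)
class TaxonRecord:
    """One species with taxonomy, ability flags and growth optima."""

    species: str
    genus: str
    order: str = ""
    diether_ability: str = UNKNOWN
    tetraether_ability: str = UNKNOWN
    category: str = UNSET
    t_opt_c: float = float("nan")
    ph_opt: float = float("nan")
    nacl_opt_pct: float = float("nan")

    def __post_init__(self) -> None:
        for a in (self.diether_ability, self.tetraether_ability):
            if a not in _ABILITIES:
                raise ValueError(f"{self.species}: unknown ability state {a!r}")


def propagate_genus_rule(
    records: Sequence[TaxonRecord], rank: str = "genus"
) -> list[TaxonRecord]:
    """Propagate observed abilities across a taxonomic rank by parsimony.

    Within each group at ``rank`` (``"genus"`` or ``"order"``), any
    *observed* diether (resp. tetraether) ability upgrades co-group
    *unknown* flags to *assumed*; *absent* and *observed* are never
    touched.  Monotone and idempotent.
    """
    if rank not in ("genus", "order"):
        raise ValueError("rank must be 'genus' or 'order'")
    has_obs: dict[str, dict[str, bool]] = {}
    for rec in records:
        key = getattr(rec, rank)
        if not key:
            raise ValueError(f"{rec.species}: empty {rank} label")
        flags = has_obs.setdefault(key, {"die": False, "tet": False})
        flags["die"] |= rec.diether_ability == OBSERVED
        flags["tet"] |= rec.tetraether_ability == OBSERVED

    out = []
    for rec in records:
        flags = has_obs[getattr(rec, rank)]
        die = ASSUMED if (rec.diether_ability == UNKNOWN and flags["die"]) else rec.diether_ability
        tet = ASSUMED if (rec.tetraether_ability == UNKNOWN and flags["tet"]) else rec.tetraether_ability
        out.append(replace(rec, diether_ability=die, tetraether_ability=tet))
    return out


def categorize_membrane(
    subject: TaxonRecord | CompositionProfile | Mapping[str, float],
    trace_threshold: float = 1.0,
) -> str:
    """Assign one of the three membrane categories.

    From a composition: tetraether total 0 -> diether_only; diether total
    below ``trace_threshold`` (%) -> tetraether_dominant; otherwise mixed.
    From ability flags: a class counts as present when observed or assumed;
    both classes unavailable raises.
    """
    if trace_threshold <= 0:
        raise ValueError("trace_threshold must be positive")
    if isinstance(subject, TaxonRecord):
        die = subject.diether_ability in (OBSERVED, ASSUMED)
        tet = subject.tetraether_ability in (OBSERVED, ASSUMED)
        if not die and not tet:
            raise ValueError(f"{subject.species}: no lipid class present or assumed")
        if not tet:
            return DIETHER_ONLY
        if not die:
            return TETRAETHER_DOMINANT
        return MIXED

    values = subject.values if isinstance(subject, CompositionProfile) else subject
    die_total = sum(v for k, v in values.items() if _skeleton_class(k) == "dgd")
    tet_total = sum(v for k, v in values.items() if _skeleton_class(k) != "dgd")
    if die_total <= 0 and tet_total <= 0:
        raise ValueError("empty composition")
    if tet_total <= 0:
        return DIETHER_ONLY
    if die_total < trace_threshold:
        return TETRAETHER_DOMINANT
    return MIXED


def category_medians(
    records: Sequence[TaxonRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-category medians of optimal growth T, pH and NaCl.

    Standard midpoint median (mean of the two central values for even
    counts); missing growth values are skipped per variable.  Categories
    with no records are omitted with a warning.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            {"category": [r.category for r in records],
             "t_opt_c": [r.t_opt_c for r in records],
             "ph_opt": [r.ph_opt for r in records],
             "nacl_opt_pct": [r.nacl_opt_pct for r in records]}
        )
    present = df[df["category"] != UNSET] if "category" in df else df
    for cat in (DIETHER_ONLY, MIXED, TETRAETHER_DOMINANT):
        if cat not in set(present["category"]):
            warnings.warn(f"category {cat!r} has no records; omitted", stacklevel=2)
    med = present.groupby("category")[["t_opt_c", "ph_opt", "nacl_opt_pct"]].median()
    return med


def round_to_ten(x: float) -> int:
    """Round to the nearest ten, halves away from zero (45 -> 50, -45 -> -50)."""
    return int(math.copysign(math.floor(abs(x) / 10.0 + 0.5) * 10, x)) if x else 0


def ancestral_composition(
    class_total_table: pd.DataFrame,
    basal_species: Sequence[str],
) -> dict[str, float]:
    """Estimate an ancestral diether/tetraether split from basal lineages.

    Averages the dgd total and the summed tetraether totals
    (gdgt + gmgt + gtgt) over the listed basal species; reports both the
    raw means and their nearest-ten roundings.  Order of ``basal_species``
    is irrelevant; missing species raise with their names.
    """
    missing = [s for s in basal_species if s not in class_total_table.index]
    if missing:
        raise KeyError(f"basal species not in table: {missing}")
    if not basal_species:
        raise ValueError("basal_species is empty")
    sub = class_total_table.loc[list(set(basal_species))]
    dgd = float(sub["dgd"].mean())
    tet = float((sub["gdgt"] + sub["gmgt"] + sub["gtgt"]).mean())
    return {
        "dgd_mean": dgd,
        "tetraether_mean": tet,
        "dgd_rounded": round_to_ten(dgd),
        "tetraether_rounded": round_to_ten(tet),
        "n_basal": len(set(basal_species)),
    }


def count_by_filter(
    states: pd.DataFrame,
    predicate: Mapping,
) -> tuple[int, list[str]]:
    """Count strains whose detection states satisfy a declarative predicate.

    ``states`` is a strains x lipids frame of state literals; a lipid is
    *detected* when its state is not ND (TRACE counts as detected).
    Predicates are nestable dicts::

        {"any": ["GMGT-0", "GMGT-1", "GDGT-1"]}     # any listed lipid detected
        {"all": ["DGD", "GDGT-0"]}                  # all listed lipids detected
        {"and": [p1, p2]} / {"or": [p1, p2]} / {"not": p}

    Returns ``(count, matching strain ids)``.
    """
    detected = states.notna() & (states != ND) & (states != "ND")

    def evaluate(pred: Mapping) -> pd.Series:
        if not isinstance(pred, Mapping) or len(pred) != 1:
            raise ValueError(f"predicate must be a single-key mapping, got {pred!r}")
        (op, arg), = pred.items()
        if op in ("any", "all"):
            if not arg:
                raise ValueError(f"empty lipid list for {op!r}")
            unknown = [l for l in arg if l not in states.columns]
            if unknown:
                raise KeyError(f"unknown lipid id(s) in predicate: {unknown}")
            block = detected[list(arg)]
            return block.any(axis=1) if op == "any" else block.all(axis=1)
        if op in ("and", "or"):
            if not arg:
                raise ValueError(f"empty term list for {op!r}")
            parts = [evaluate(p) for p in arg]
            out = parts[0]
            for p in parts[1:]:
                out = (out & p) if op == "and" else (out | p)
            return out
        if op == "not":
            return ~evaluate(arg)
        if op == "true":
            return pd.Series(True, index=states.index)
        raise ValueError(f"unknown predicate operator {op!r}")

    hit = evaluate(predicate)
    ids = [str(s) for s in states.index[hit]]
    return len(ids), ids
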