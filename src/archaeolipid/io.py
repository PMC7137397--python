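"""Readers, writers, the packaged composition table and run configuration.

One tabular dialect everywhere: tab-separated UTF-8 with '.' decimals,
``ND``/``Traces`` literals for detection states and empty cells for missing
values.  Mean and sd are always separate columns; the "+/-" notation of
printed tables is never parsed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd

from .quantify import ND, QUANT, TRACE, CompositionProfile

__all__ = [
    "LIPID_COLUMNS", "CompositionTable",
    "load_table1_fixture", "read_composition_table", "write_composition_table",
    "read_env_table", "write_env_table",
    "read_taxon_table", "write_taxon_table",
    "read_newick", "write_newick",
    "RunConfig", "load_config",
]

#: canonical column order of the quantified core lipids
LIPID_COLUMNS = ["DGD", "GDGT-0", "GDGT-1", "GDGT-2", "GDGT-3", "GDGT-4",
                 "GMGT-0", "GMGT-1", "GTGT-0", "GTGT-1"]

#: sha256 of the packaged 51-strain composition table; guards against a
#: silently corrupted installation
_TABLE1_SHA256 = "02c0fd82ed0ef39fd7ce52309f92cfb73c0d00e7835c39914b7e73b41de7bcdc"

#: alternate spellings of strain names accepted on input
STRAIN_SYNONYMS = {
    "T. sp. P6": "Thermococcus sp. P6",
    "T. sp. AM4": "Thermococcus sp. AM4",
    "T. sp. DT4": "Thermococcus sp. DT4",
    "P. furiosus": "Pyrococcus furiosus",
}


@dataclass
class CompositionTable:
    """Strains x lipids composition with sd and ND/TRACE/QUANT states."""

    values: pd.DataFrame   # percentages; NaN where not quantified
    sd: pd.DataFrame       # replicate sd; NaN where not quantified
    states: pd.DataFrame   # "ND" / "TRACE" / "QUANT"
    genus: pd.Series       # genus label per strain

    @property
    def strains(self) -> list[str]:
        return [str(s) for s in self.values.index]

    def profiles(self) -> list[CompositionProfile]:
        out = []
        for strain in self.values.index:
            vals, states = {}, {}
            for lid in self.values.columns:
                st = self.states.at[strain, lid]
                states[lid] = st
                if st == QUANT:
                    vals[lid] = float(self.values.at[strain, lid])
            out.append(CompositionProfile(strain=str(strain), values=vals, states=states))
        return out

    def validate(self, tol: float = 0.5) -> None:
        sums = self.values.sum(axis=1, skipna=True)
        bad = sums[(sums - 100.0).abs() > tol]
        if len(bad):
            worst = bad.index[0]
            raise ValueError(
                f"{len(bad)} strain(s) do not close to 100 +/- {tol} "
                f"(e.g. {worst}: {bad.iloc[0]:.1f})"
            )


def _table_from_wide(df: pd.DataFrame, source: str) -> CompositionTable:
    missing_cols = [c for c in ("strain", "genus") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{source}: missing column(s) {missing_cols}")
    df = df.copy()
    df["strain"] = df["strain"].map(lambda s: STRAIN_SYNONYMS.get(s, s))
    if df["strain"].duplicated().any():
        raise ValueError(f"{source}: duplicate strain names")
    df = df.set_index("strain")
    values = pd.DataFrame(index=df.index, columns=LIPID_COLUMNS, dtype=float)
    sd = pd.DataFrame(index=df.index, columns=LIPID_COLUMNS, dtype=float)
    states = pd.DataFrame(index=df.index, columns=LIPID_COLUMNS, dtype=object)
    for lid in LIPID_COLUMNS:
        if lid not in df.columns:
            raise ValueError(f"{source}: missing lipid column {lid!r}")
        raw = df[lid].astype(str).str.strip()
        sd_col = df.get(f"{lid}_sd")
        for strain, cell in raw.items():
            if cell in ("ND", "nan", ""):
                states.at[strain, lid] = ND
            elif cell.lower() == "traces":
                states.at[strain, lid] = TRACE
            else:
                try:
                    values.at[strain, lid] = float(cell)
                except ValueError:
                    line = df.index.get_loc(strain) + 2
                    raise ValueError(
                        f"{source}: line {line}: cannot parse {lid}={cell!r}"
                    ) from None
                states.at[strain, lid] = QUANT
                if sd_col is not None and pd.notna(sd_col.loc[strain]):
                    sd.at[strain, lid] = float(sd_col.loc[strain])
    return CompositionTable(values=values, sd=sd, states=states, genus=df["genus"])


def read_composition_table(path: str | Path) -> CompositionTable:
    """Read a wide composition TSV (strain, genus, <lipid>, <lipid>_sd ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _table_from_wide(df, str(path))


def write_composition_table(table: CompositionTable, path: str | Path) -> None:
    """Write a wide composition TSV; inverse of :func:`read_composition_table`."""
    cols: dict[str, list] = {"strain": table.strains, "genus": list(table.genus)}
    for lid in table.values.columns:
        vals, sds = [], []
        for strain in table.values.index:
            st = table.states.at[strain, lid]
            if st == QUANT:
                vals.append(np.format_float_positional(table.values.at[strain, lid], trim="-"))
                s = table.sd.at[strain, lid]
                sds.append("" if pd.isna(s) else np.format_float_positional(s, trim="-"))
            elif st == TRACE:
                vals.append("Traces")
                sds.append("")
            else:
                vals.append("ND")
                sds.append("")
        cols[lid] = vals
        cols[f"{lid}_sd"] = sds
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def load_table1_fixture() -> CompositionTable:
    """Load the packaged 51-strain core-lipid composition table.

    Verifies the file checksum, parses ND/Traces states and checks that
    quantified rows close to 100% within the transcription tolerance
    (+/- 2.5; a few printed rows do not close more tightly than that).
    """
    ref = resources.files("archaeolipid").joinpath("data/table1.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise ValueError(
            f"packaged composition table checksum mismatch ({digest}); corrupted install?"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t", dtype=str)
    table = _table_from_wide(df, "table1.tsv")
    if len(table.strains) != 51:
        raise ValueError(f"expected 51 strains, found {len(table.strains)}")
    table.validate(tol=2.5)
    return table


def write_aggregate_tsv(aggregates: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Write per-strain replicate summaries as a long TSV.

    ``aggregates`` maps strain -> frame from
    :func:`archaeolipid.quantify.aggregate_replicates`; columns are strain,
    lipid_id, mean_pct, sd_pct, state.
    """
    frames = []
    for strain, agg in aggregates.items():
        f = agg.reset_index()
        f.insert(0, "strain", strain)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_env_table(path: str | Path):
    """Read an environment table TSV (first column strain, empty = missing)."""
    from .simulate import EnvTable

    df = pd.read_csv(path, sep="\t", index_col=0)
    return EnvTable(data=df, mask=df.isna())


def write_env_table(env, path: str | Path) -> None:
    env.data.to_csv(path, sep="\t", na_rep="")


def read_taxon_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"species", "genus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_taxon_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_newick(path: str | Path) -> str:
    """Read and syntax-check a newick tree, returning the newick string."""
    import dendropy

    text = Path(path).read_text(encoding="utf-8").strip()
    try:
        dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValueError(f"{path}: unparseable newick: {exc}") from exc
    return text


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip() + "\n", encoding="utf-8")


# --- run configuration -----------------------------------------------------

from pydantic import BaseModel, ConfigDict, Field


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class QuantifyConfig(_Block):
    min_snr: float = Field(3.0, gt=0)
    mz_tol: float = Field(0.5, gt=0)
    trace_cutoff: float = Field(0.05, gt=0)


class StatsConfig(_Block):
    n_components: int = Field(5, gt=0)
    tol: float = Field(1e-6, gt=0)
    max_iter: int = Field(1000, gt=0)
    distance: str = "euclidean"
    linkage: str = "average"
    ridge: float = Field(0.0, ge=0)


class TraitsConfig(_Block):
    rank: str = "genus"
    trace_threshold: float = Field(1.0, gt=0)


class RunConfig(_Block):
    """Validated run configuration; unknown keys are rejected."""

    seed: int = 0
    quantify: QuantifyConfig = QuantifyConfig()
    stats: StatsConfig = StatsConfig()
    traits: TraitsConfig = TraitsConfig()
    paths: dict[str, str] = Field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
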