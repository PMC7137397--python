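"""Synthetic inputs for every pipeline stage.

Nothing downstream of this module needs an instrument or a download: it
emulates (i) extracted-ion chromatograms of archaeal core lipids,
(ii) biological replicate compositions, (iii) environment/growth tables
with a controlled correlation structure and MCAR missingness, and
(iv) small taxonomies with known lipid-synthesis abilities.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import QUANT, CompositionProfile
from .registry import LipidSpecies, default_registry

__all__ = [
    "ChromatogramSet", "EnvTable",
    "simulate_chromatogram", "simulate_replicates", "simulate_env_lipid",
    "make_taxonomy_fixture", "simulate_archaeal_survey",
    "simulate_thermococcales_cohort", "attach_env_columns",
    "SURVEY_CATEGORY_MEDIANS", "FIG2B_TARGET_CORRELATIONS",
]

SCAN_RANGE = (600.0, 2200.0)  # m/z window of the emulated instrument


@dataclass
class ChromatogramSet:
    """Per-m/z-channel intensity traces for one injection."""

    time_grid: np.ndarray                      # min, uniform
    channels: dict[float, np.ndarray]          # mz -> counts
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mz, trace in self.channels.items():
            if not SCAN_RANGE[0] <= mz <= SCAN_RANGE[1]:
                raise ValueError(f"channel m/z {mz} outside scan range {SCAN_RANGE}")
            if trace.shape != self.time_grid.shape:
                raise ValueError("all channels must share the time grid")
            if np.any(trace < 0):
                raise ValueError("intensities must be non-negative")

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV: channel_mz, time, intensity."""
        frames = [
            pd.DataFrame({"channel_mz": mz, "time": self.time_grid, "intensity": trace})
            for mz, trace in sorted(self.channels.items())
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChromatogramSet":
        df = pd.read_csv(path, sep="\t")
        channels = {}
        grid = None
        for mz, sub in df.groupby("channel_mz"):
            t = sub["time"].to_numpy(dtype=float)
            if grid is None:
                grid = t
            elif not np.array_equal(grid, t):
                raise ValueError(f"{path}: channels disagree on the time grid")
            channels[float(mz)] = sub["intensity"].to_numpy(dtype=float)
        if grid is None:
            raise ValueError(f"{path}: empty chromatogram file")
        return cls(time_grid=grid, channels=channels)


@dataclass
class EnvTable:
    """Strains x environmental/growth parameters with a missingness mask."""

    data: pd.DataFrame    # NaN where missing
    mask: pd.DataFrame    # True where missing

    def __post_init__(self) -> None:
        if not self.data.shape == self.mask.shape:
            raise ValueError("data and mask shapes differ")
        if not (self.data.isna() == self.mask).all().all():
            raise ValueError("mask inconsistent with NaN pattern")
        if self.mask.all(axis=0).any():
            raise ValueError("entirely-missing column")


def simulate_chromatogram(
    true_molar_composition: Mapping[str, float],
    registry: Sequence[LipidSpecies] | None = None,
    noise_sd: float = 0.0,
    peak_width_sd: float = 0.1,
    seed: int | None = None,
    total_signal: float = 1e6,
    time_step: float = 0.005,
) -> ChromatogramSet:
    """Emulate one HPLC-APCI-MS injection.

    Each species with a positive molar fraction contributes a Gaussian peak
    on its own m/z channel at its nominal retention time, with area
    ``fraction * response_factor * total_signal`` — so the simulated
    detector under-reports diethers exactly as the real one does.  With
    ``noise_sd > 0`` a constant detector offset of ``5 * noise_sd`` plus
    additive Gaussian noise is applied and intensities are clipped at zero.
    """
    registry = list(registry) if registry is not None else default_registry()
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if peak_width_sd <= 0:
        raise ValueError("peak_width_sd must be positive")
    by_id = {s.id: s for s in registry}
    unknown = [k for k in true_molar_composition if k not in by_id]
    if unknown:
        raise KeyError(f"unknown lipid id(s): {unknown}")
    total = sum(true_molar_composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"molar fractions must sum to 1 (got {total})")

    t_max = max(s.rt_center for s in registry) + 8 * peak_width_sd + 1.0
    grid = np.arange(0.0, t_max, time_step)
    rng = np.random.default_rng(seed)
    channels: dict[float, np.ndarray] = {s.mz_proton: np.zeros_like(grid) for s in registry}
    for lid, frac in true_molar_composition.items():
        if frac <= 0:
            continue
        sp = by_id[lid]
        area = frac * sp.response_factor * total_signal
        height = area / (peak_width_sd * math.sqrt(2.0 * math.pi))
        channels[sp.mz_proton] += height * np.exp(
            -0.5 * ((grid - sp.rt_center) / peak_width_sd) ** 2
        )
    if noise_sd > 0:
        for mz in channels:
            channels[mz] = np.clip(
                channels[mz] + 5.0 * noise_sd + rng.normal(0.0, noise_sd, grid.shape), 0.0, None
            )
    return ChromatogramSet(
        time_grid=grid, channels=channels,
        metadata={"seed": seed, "noise_sd": noise_sd, "peak_width_sd": peak_width_sd},
    )


def simulate_replicates(
    profile: CompositionProfile,
    dispersion: float,
    n: int = 3,
    seed: int | None = None,
) -> list[CompositionProfile]:
    """Logistic-normal biological replicates of a closed composition.

    Log abundances are perturbed with i.i.d. Gaussian noise of standard
    deviation ``dispersion`` and re-closed to 100%; ``dispersion = 0``
    returns exact copies.  The default ``n = 3`` matches a triplicate
    culture design.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    # printed reference rows close only to ~2.5; replicates re-close exactly
    profile.validate(tol=2.5)
    ids = sorted(profile.values)
    p = np.array([profile.values[i] for i in ids], dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        logp = np.log(p) + rng.normal(0.0, dispersion, p.shape)
        q = np.exp(logp - logp.max())
        q = 100.0 * q / q.sum()
        out.append(
            CompositionProfile(
                strain=profile.strain,
                values=dict(zip(ids, q.tolist())),
                states={**profile.states, **{i: QUANT for i in ids}},
            )
        )
    return out


def simulate_env_lipid(
    n_strains: int,
    n_env: int,
    n_lipid: int,
    rho: Sequence[float],
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[EnvTable, pd.DataFrame, pd.DataFrame]:
    """Two data blocks with known population canonical correlations.

    Shared latent variables give the j-th env/lipid column pair a
    correlation of ``rho[j]``; all other columns are independent noise, so
    the population canonical correlations are exactly ``rho`` (sorted
    descending).  Env columns are affinely shifted/scaled to be positive,
    matching the physical nature of such measurements; an MCAR mask at
    ``missing_rate`` is applied to the env block only.

    Returns ``(env_table, lipid_frame, mask)``.
    """
    rho = list(rho)
    if any(not 0.0 <= r < 1.0 for r in rho):
        raise ValueError("each rho must lie in [0, 1)")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    k = len(rho)
    if k > min(n_env, n_lipid):
        raise ValueError("len(rho) may not exceed min(n_env, n_lipid)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_strains, k))
    x = rng.standard_normal((n_strains, n_env))
    y = rng.standard_normal((n_strains, n_lipid))
    for j, r in enumerate(rho):
        x[:, j] = z[:, j]
        y[:, j] = r * z[:, j] + math.sqrt(1.0 - r * r) * y[:, j]

    env_cols = [f"env_{j}" for j in range(n_env)]
    lip_cols = [f"lipid_{j}" for j in range(n_lipid)]
    idx = [f"strain_{i}" for i in range(n_strains)]
    env = pd.DataFrame(10.0 + 2.0 * x, index=idx, columns=env_cols).clip(lower=0.01)
    lip = pd.DataFrame(25.0 + 5.0 * y, index=idx, columns=lip_cols).clip(lower=0.01)
    mask = pd.DataFrame(rng.random((n_strains, n_env)) < missing_rate,
                        index=idx, columns=env_cols)
    # keep the no-all-missing-column invariant even at high rates
    for c in env_cols:
        if mask[c].all():
            mask.loc[mask.index[0], c] = False
    env = env.mask(mask)
    return EnvTable(data=env, mask=mask), lip, mask


def make_taxonomy_fixture(seed: int | None = None) -> tuple[pd.DataFrame, str]:
    """A 3-genus, 12-species taxonomy with known abilities plus a tree.

    The ``Methanococcus``-like genus has three diether-only records whose
    tetraether ability is unknown and one confirmed tetraether producer, so
    genus-level parsimony propagation has something to do; the halophile
    genus is diether-only with tetraether ability *absent* (never to be
    overwritten); the ``Thermococcus``-like genus has both abilities
    observed.  Growth optima are jittered deterministically from the seed.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(species, genus, order, die, tet, t, ph, nacl):
        rows.append((species, genus, order, die, tet,
                     round(t + rng.normal(0, 1.0), 1),
                     round(ph + rng.normal(0, 0.1), 2),
                     round(max(0.0, nacl + rng.normal(0, 0.2)), 2)))

    for i, tet in enumerate(["unknown", "unknown", "unknown", "observed"]):
        add(f"Methanococcus sp{i+1}", "Methanococcus", "Methanococcales",
            "observed", tet, 38, 7.0, 2.0)
    for i in range(4):
        add(f"Thermococcus sp{i+1}", "Thermococcus", "Thermococcales",
            "observed", "observed", 85, 7.0, 3.0)
    for i in range(4):
        add(f"Haloferax sp{i+1}", "Haloferax", "Haloferacales",
            "observed", "absent", 40, 7.3, 20.0)
    df = pd.DataFrame(rows, columns=[
        "species", "genus", "order", "diether_ability", "tetraether_ability",
        "t_opt_c", "ph_opt", "nacl_opt_pct",
    ])

    def clade(genus: str) -> str:
        leaves = [s.replace(" ", "_") for s in df.species[df.genus == genus]]
        return "(" + ",".join(f"{s}:1" for s in leaves) + f"):1"

    newick = f"({clade('Methanococcus')},{clade('Thermococcus')},{clade('Haloferax')});"
    return df, newick


#: per-category medians of optimal growth conditions (T degC, pH, NaCl %)
#: used as the population parameters of the survey generator
SURVEY_CATEGORY_MEDIANS = {
    "tetraether_dominant": {"t_opt_c": 80.0, "ph_opt": 3.6, "nacl_opt_pct": 0.0},
    "mixed": {"t_opt_c": 80.0, "ph_opt": 7.0, "nacl_opt_pct": 2.3},
    "diether_only": {"t_opt_c": 38.0, "ph_opt": 7.3, "nacl_opt_pct": 20.0},
}

#: category sizes for the 440-species survey: 248 halophiles + A. pernix +
#: 6 diether-only methanogens = 255 diether-only; the remaining 185
#: mixed-lipid species are split 140 mixed / 45 tetraether-dominant
SURVEY_CATEGORY_COUNTS = {"diether_only": 255, "mixed": 140, "tetraether_dominant": 45}


def simulate_archaeal_survey(
    counts: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic domain-wide lipid survey (default 440 records).

    Each record carries a membrane category (diether_only / mixed /
    tetraether_dominant) and optimal growth conditions drawn around the
    category medians in :data:`SURVEY_CATEGORY_MEDIANS` with symmetric
    noise, so the population medians are the stated values: halophilic
    diether-only species centre on 38 degC / pH 7.3 / 20% NaCl,
    thermoneutrophilic mixed species on 80 / 7.0 / 2.3, and
    thermoacidophilic tetraether-dominant species on 80 / 3.6 / 0.
    """
    counts = dict(counts) if counts is not None else dict(SURVEY_CATEGORY_COUNTS)
    rng = np.random.default_rng(seed)
    rows = []
    for cat, n in counts.items():
        med = SURVEY_CATEGORY_MEDIANS[cat]
        t = med["t_opt_c"] + rng.normal(0, 8.0, n)
        ph = np.clip(med["ph_opt"] + rng.normal(0, 0.6, n), 0.5, 13.5)
        if med["nacl_opt_pct"] == 0.0:
            nacl = np.where(rng.random(n) < 0.6, 0.0, rng.exponential(0.5, n))
        else:
            nacl = np.clip(med["nacl_opt_pct"] + rng.normal(0, med["nacl_opt_pct"] * 0.25, n), 0.0, None)
        die = "observed"
        tet = "absent" if cat == "diether_only" else "observed"
        for i in range(n):
            rows.append((f"{cat}_sp{i+1}", f"{cat}_genus{i % 40}", f"{cat}_order",
                         die, tet, cat, float(t[i]), float(ph[i]), float(nacl[i])))
    df = pd.DataFrame(rows, columns=[
        "species", "genus", "order", "diether_ability", "tetraether_ability",
        "category", "t_opt_c", "ph_opt", "nacl_opt_pct",
    ])
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31)) ).reset_index(drop=True)


#: lipid-vs-environment correlations used as population targets for the
#: synthetic Thermococcales growth/environment table (rows: env variables;
#: entries: target Pearson r with each lipid class total / RI).  Only the
#: listed pairs are controlled; correlations with the remaining class
#: totals follow from compositional closure and are left free (a closed
#: composition cannot realise arbitrary correlation vectors).
FIG2B_TARGET_CORRELATIONS = {
    "t_opt_c": {"dgd": -0.46, "gdgt": 0.34, "ri": 0.23},
    "depth_m": {"dgd": 0.20},
    "t_insitu_c": {"gmgt": -0.41},
    "nacl_opt_pct": {"gmgt": -0.54},
    "ph_opt": {},
    "ph_insitu": {},
    # vent ion chemistry: present in the env block (these are the sparsely
    # measured variables imputation exists for) but not correlation-controlled
    "sr_um": {},
    "fe_um": {},
    "mn_um": {},
    "h2s_mm": {},
}

#: affine (loc, scale) mapping each standardized env variable to realistic units
_ENV_UNITS = {
    "t_opt_c": (85.0, 8.0),
    "depth_m": (2200.0, 700.0),
    "t_insitu_c": (120.0, 60.0),
    "nacl_opt_pct": (3.0, 0.8),
    "ph_opt": (6.8, 0.6),
    "ph_insitu": (5.5, 1.0),
    "sr_um": (90.0, 30.0),
    "fe_um": (750.0, 400.0),
    "mn_um": (500.0, 250.0),
    "h2s_mm": (4.0, 2.0),
}


def attach_env_columns(
    lipid: pd.DataFrame,
    targets: Mapping[str, Mapping[str, float]] | None = None,
    missing_rate: float = 0.0,
    seed: int | None = None,
    ridge: float = 1e-6,
) -> EnvTable:
    """Build an environment table correlated with a given lipid matrix.

    For each env variable, only the lipid columns listed in its target
    mapping are constrained: with ``c`` the target vector over those
    columns and ``R`` their (standardized) correlation sub-matrix, the
    latent env value is ``L_c @ (R^-1 c) + sqrt(1 - c' R^-1 c) * z``, whose
    correlation with each constrained column equals ``c`` up to sampling
    noise in ``z``.  Correlations with the unlisted columns follow from the
    compositional geometry (closure makes arbitrary full vectors
    infeasible).  Raises if a target vector is infeasible
    (``c' R^-1 c >= 1``).  Values are mapped to positive physical units and
    an MCAR mask is applied.
    """
    targets = targets if targets is not None else FIG2B_TARGET_CORRELATIONS
    rng = np.random.default_rng(seed)
    L = lipid.to_numpy(dtype=float)
    L = (L - L.mean(axis=0)) / L.std(axis=0)
    n = L.shape[0]
    colpos = {c_: i for i, c_ in enumerate(lipid.columns)}
    cols = {}
    for env_name, spec_corr in targets.items():
        unknown = set(spec_corr) - set(lipid.columns)
        if unknown:
            raise KeyError(f"{env_name}: unknown lipid column(s) {sorted(unknown)}")
        if spec_corr:
            sel = [colpos[c_] for c_ in spec_corr]
            Ls = L[:, sel]
            R = Ls.T @ Ls / n + ridge * np.eye(len(sel))
            c = np.array(list(spec_corr.values()))
            w = np.linalg.solve(R, c)
            s2 = 1.0 - float(c @ w)
            if s2 <= 0:
                raise ValueError(
                    f"{env_name}: target correlations infeasible for these lipid data"
                )
            e = Ls @ w + math.sqrt(s2) * rng.standard_normal(n)
        else:
            e = rng.standard_normal(n)
        loc, scale = _ENV_UNITS.get(env_name, (10.0, 2.0))
        cols[env_name] = np.clip(loc + scale * e, 0.01, None)
    env = pd.DataFrame(cols, index=lipid.index)
    mask = pd.DataFrame(rng.random(env.shape) < missing_rate,
                        index=env.index, columns=env.columns)
    for c_ in env.columns:
        if mask[c_].all():
            mask.loc[mask.index[0], c_] = False
    return EnvTable(data=env.mask(mask), mask=mask)


def simulate_thermococcales_cohort(
    n_strains: int = 1000,
    dispersion: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Class-total matrix (dgd/gdgt/gmgt/gtgt/ri) for a synthetic cohort.

    Pseudo-strains are drawn by resampling the packaged 51-strain
    composition table with logistic-normal jitter, so the cohort inherits
    the real marginal lipid distribution (its strong dgd/gdgt trade-off
    included) at arbitrary sample size.
    """
    from .io import load_table1_fixture
    from .stats import class_totals_table

    table = load_table1_fixture()
    base = class_totals_table(table.profiles())
    cols = ["dgd", "gdgt", "gmgt", "gtgt"]
    vals = base[cols].to_numpy(dtype=float)
    ris = base["ri"].fillna(0.0).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, len(vals), n_strains)
    eps = 1e-3  # floor so zero classes stay zero-ish but logs are defined
    logv = np.log(vals[pick] + eps) + rng.normal(0, dispersion, (n_strains, len(cols)))
    q = np.exp(logv)
    q = 100.0 * q / q.sum(axis=1, keepdims=True)
    ri = np.clip(ris[pick] * np.exp(rng.normal(0, dispersion, n_strains)), 0.0, 4.0)
    idx = [f"pseudo_{i}" for i in range(n_strains)]
    out = pd.DataFrame(q, columns=cols, index=idx)
    out["ri"] = ri
    return out
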