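"""Chromatogram -> closed, response-corrected core-lipid composition.

The quantification contract mirrors how relative abundances are obtained
from HPLC-APCI-MS extracted-ion chromatograms of archaeal core lipids:

1. peaks are detected and integrated per m/z channel (:func:`detect_peaks`),
2. each peak is assigned to a registry structure by m/z, with isobaric
   structures resolved by elution order (:func:`identify_peaks`),
3. areas are converted to molar amounts with per-class response factors —
   diethers respond ~10x weaker than tetraethers — and closed to 100%
   (:func:`correct_and_close`),
4. species are labelled ND (no peak), TRACE (below the quantification
   cutoff) or QUANT, re-closing over the quantified species
   (:func:`assign_states`),
5. biological replicates are summarised as mean +/- sd
   (:func:`aggregate_replicates`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .registry import LipidSpecies

__all__ = [
    "ND", "TRACE", "QUANT",
    "Peak", "CompositionProfile", "CoelutionError",
    "detect_peaks", "identify_peaks", "correct_and_close",
    "estimate_response_factor", "assign_states",
    "quantify_chromatogram", "aggregate_replicates",
]

ND = "ND"
TRACE = "TRACE"
QUANT = "QUANT"


class CoelutionError(ValueError):
    """Two peaks compete for one non-isobaric structure."""


@dataclass(frozen=True)
class Peak:
    """One integrated chromatographic peak."""

    channel_mz: float   # Da
    apex_time: float    # min
    area: float         # counts * min
    snr: float          # apex height / baseline noise; inf for noiseless traces

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("peak area must be positive")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


@dataclass
class CompositionProfile:
    """One strain's closed relative-abundance vector with detection states.

    ``values`` holds percentages for QUANT species only; TRACE species are
    detected but carry no number, ND species were not detected at all.
    """

    strain: str
    values: dict[str, float] = field(default_factory=dict)
    states: dict[str, str] = field(default_factory=dict)

    def value(self, lipid_id: str, default: float = 0.0) -> float:
        """Numeric abundance, treating TRACE and ND as ``default`` (0)."""
        return self.values.get(lipid_id, default)

    def quant_sum(self) -> float:
        return float(sum(self.values.values()))

    def validate(self, tol: float = 0.5) -> None:
        for lid in self.values:
            if self.states.get(lid, QUANT) != QUANT:
                raise ValueError(f"{self.strain}: {lid} has a value but state is not QUANT")
        s = self.quant_sum()
        if self.values and abs(s - 100.0) > tol:
            raise ValueError(f"{self.strain}: quantified values sum to {s:.2f}, not 100 +/- {tol}")


def detect_peaks(
    time: np.ndarray,
    intensity: np.ndarray,
    channel_mz: float = float("nan"),
    min_snr: float = 3.0,
    smooth_window: int = 9,
) -> list[Peak]:
    """Detect and integrate peaks on one extracted-ion channel.

    Apex detection runs on a moving-average-smoothed copy of the trace
    (``smooth_window`` points) so single-sample noise spikes do not
    register as peaks; integration uses the raw trace.  Baseline is the
    smoothed-trace median; noise is its scaled median absolute deviation
    (1.4826 * MAD).  Local maxima higher than
    ``baseline + min_snr * noise`` are kept, and each peak is integrated by
    the trapezoidal rule between its valley boundaries (the nearest local
    minima, tightened to where the trace returns into the noise band).

    Requires a uniform time grid; peaks are returned sorted by apex time.
    """
    time = np.asarray(time, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if time.ndim != 1 or time.shape != intensity.shape:
        raise ValueError("time and intensity must be 1-D arrays of equal length")
    if min_snr <= 0:
        raise ValueError("min_snr must be positive")
    steps = np.diff(time)
    if len(steps) == 0:
        return []
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        raise ValueError("time grid is not uniform")

    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(intensity, kernel, mode="same")
    else:
        smoothed = intensity
    baseline = float(np.median(intensity))
    # noise of the raw trace: smoothing suppresses it ~sqrt(window)-fold, so
    # a raw-noise threshold applied to the smoothed trace rejects spikes
    noise = 1.4826 * float(np.median(np.abs(intensity - baseline)))
    # noiseless traces: any rise above baseline counts, guarded by a tiny
    # relative epsilon so flat traces yield nothing
    span = float(smoothed.max() - baseline)
    if span <= 0:
        return []
    height = baseline + max(min_snr * noise, 1e-9 * span)
    # distance merges noisy double-tops of one peak; prominence rejects
    # bumps riding on the shoulder of a larger peak
    apexes, _ = _signal.find_peaks(
        smoothed, height=height,
        distance=max(smooth_window, 2),
        prominence=max(min_snr * noise, 1e-9 * span),
    )
    if len(apexes) == 0:
        return []

    floor = baseline + noise  # integration stops once the trace is back in the noise
    peaks: list[Peak] = []
    for k, apex in enumerate(apexes):
        left = apexes[k - 1] if k > 0 else 0
        right = apexes[k + 1] if k + 1 < len(apexes) else len(smoothed) - 1
        # valley: lowest point between neighbouring apexes (or grid edge)
        lo = int(np.argmin(smoothed[left:apex + 1])) + left if apex > left else left
        hi = int(np.argmin(smoothed[apex:right + 1])) + apex if right > apex else right
        # tighten to where the trace re-enters the noise band
        seg = smoothed[lo:hi + 1]
        below = np.nonzero(seg <= floor)[0]
        ai = apex - lo
        lefts = below[below < ai]
        rights = below[below > ai]
        if len(lefts):
            lo = lo + int(lefts[-1])
        if len(rights):
            hi = (apex - ai) + int(rights[0])
        area = float(np.trapezoid(intensity[lo:hi + 1] - baseline, time[lo:hi + 1]))
        if area <= 0:
            continue
        snr = (float(smoothed[apex]) - baseline) / noise if noise > 0 else math.inf
        peaks.append(Peak(channel_mz, float(time[apex]), area, snr))
    return sorted(peaks, key=lambda p: p.apex_time)


def identify_peaks(
    peaks: Sequence[Peak],
    registry: Sequence[LipidSpecies],
    mz_tol: float = 0.5,
) -> tuple[dict[str, float], list[Peak]]:
    """Assign peaks to registry structures.

    Each peak is matched to the species whose [M+H]+ lies within ``mz_tol``
    of the peak's channel.  When several species share a channel (isobars),
    assignment preserves elution order and minimises the total
    apex-to-nominal retention-time discrepancy.  Returns ``(areas,
    unassigned)``; peaks matching no species are reported, never dropped.

    Raises :class:`CoelutionError` when more peaks than candidate species
    share a channel (an unresolved co-elution).
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    areas: dict[str, float] = {}
    unassigned: list[Peak] = []

    groups: dict[tuple[str, ...], list[Peak]] = {}
    for pk in peaks:
        cands = tuple(
            s.id for s in sorted(registry, key=lambda s: s.rt_center)
            if abs(s.mz_proton - pk.channel_mz) <= mz_tol
        )
        groups.setdefault(cands, []).append(pk)

    id_map = {s.id: s for s in registry}
    for cand_ids, pks in groups.items():
        if not cand_ids:
            unassigned.extend(pks)
            continue
        pks = sorted(pks, key=lambda p: p.apex_time)
        if len(pks) > len(cand_ids):
            raise CoelutionError(
                f"{len(pks)} peaks compete for {len(cand_ids)} structure(s) "
                f"{list(cand_ids)} near m/z {pks[0].channel_mz}"
            )
        for pk, sid in zip(pks, _order_preserving_match(pks, [id_map[c] for c in cand_ids])):
            areas[sid] = areas.get(sid, 0.0) + pk.area
    return areas, unassigned


def _order_preserving_match(pks: Sequence[Peak], cands: Sequence[LipidSpecies]) -> list[str]:
    """Match time-ordered peaks to rt-ordered candidate species.

    Chooses the candidate subset minimising the summed |apex - rt_center|
    while keeping both orders (dynamic program over candidates).
    """
    n, m = len(pks), len(cands)
    INF = math.inf
    # dp[i][j]: min cost matching first i peaks within first j candidates
    dp = [[INF] * (m + 1) for _ in range(n + 1)]
    choice = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        dp[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            skip = dp[i][j - 1]
            take = dp[i - 1][j - 1] + abs(pks[i - 1].apex_time - cands[j - 1].rt_center)
            if take <= skip:
                dp[i][j], choice[i][j] = take, 1
            else:
                dp[i][j], choice[i][j] = skip, 0
    out: list[str] = []
    i, j = n, m
    while i > 0:
        if choice[i][j]:
            out.append(cands[j - 1].id)
            i, j = i - 1, j - 1
        else:
            j -= 1
    return out[::-1]


def correct_and_close(
    areas: Mapping[str, float],
    registry: Sequence[LipidSpecies],
) -> dict[str, float]:
    """Convert areas to molar relative abundances closed to 100%.

    Molar amount_i = area_i / response_factor_i, so a diether with the
    default factor 0.1 is corrected upward 10-fold relative to tetraethers;
    percentages are amounts normalised to 100.
    """
    rf = {s.id: s.response_factor for s in registry}
    unknown = [k for k in areas if k not in rf]
    if unknown:
        raise KeyError(f"unknown lipid id(s) in areas: {unknown}")
    amounts = {k: a / rf[k] for k, a in areas.items() if a > 0}
    total = sum(amounts.values())
    if total <= 0:
        raise ValueError("all areas are zero; nothing to close")
    return {k: 100.0 * v / total for k, v in amounts.items()}


def estimate_response_factor(
    standard_areas: Mapping[str, float],
    molar_ratio: float,
    diether_id: str = "DGD",
    tetraether_id: str = "GDGT-0",
) -> float:
    """Calibrate the diether response factor from a two-lipid standard.

    For a standard mixing ``diether_id`` and ``tetraether_id`` at a known
    molar ratio (diether:tetraether), returns
    ``molar_ratio / (area_diether / area_tetraether)`` — the fold by which
    the diether under-responds.  A 2:1 molar standard whose diether peak is
    only 0.2x the tetraether peak therefore yields 10.
    """
    if molar_ratio <= 0:
        raise ValueError("molar_ratio must be positive")
    try:
        a_d, a_t = standard_areas[diether_id], standard_areas[tetraether_id]
    except KeyError as exc:
        raise KeyError(f"standard is missing an area for {exc.args[0]!r}") from None
    if a_d <= 0 or a_t <= 0:
        raise ValueError("standard areas must be positive")
    return molar_ratio / (a_d / a_t)


def assign_states(
    values: Mapping[str, float],
    all_ids: Iterable[str],
    trace_cutoff: float = 0.05,
) -> tuple[dict[str, float], dict[str, str]]:
    """Label species ND / TRACE / QUANT and re-close over QUANT species.

    ``values`` are corrected, closed percentages for the *detected* species;
    any id in ``all_ids`` absent from ``values`` is ND.  Detected species
    below ``trace_cutoff`` (%) become TRACE and are removed from the closure.
    """
    if trace_cutoff <= 0:
        raise ValueError("trace_cutoff must be positive")
    states: dict[str, str] = {}
    for lid in all_ids:
        if lid not in values:
            states[lid] = ND
        elif values[lid] < trace_cutoff:
            states[lid] = TRACE
        else:
            states[lid] = QUANT
    quant = {k: v for k, v in values.items() if states.get(k) == QUANT}
    total = sum(quant.values())
    if total <= 0:
        raise ValueError("no species above the trace cutoff")
    return {k: 100.0 * v / total for k, v in quant.items()}, states


def quantify_chromatogram(
    chromatograms,
    registry: Sequence[LipidSpecies],
    strain: str = "sample",
    min_snr: float = 3.0,
    mz_tol: float = 0.5,
    trace_cutoff: float = 0.05,
) -> CompositionProfile:
    """Full per-injection pipeline: detect, identify, correct, close, label.

    ``chromatograms`` is a :class:`~archaeolipid.simulate.ChromatogramSet`
    (or anything with ``time_grid`` and ``channels``).
    """
    peaks: list[Peak] = []
    for mz, trace in chromatograms.channels.items():
        peaks.extend(detect_peaks(chromatograms.time_grid, trace, channel_mz=mz, min_snr=min_snr))
    areas, _ = identify_peaks(peaks, registry, mz_tol=mz_tol)
    closed = correct_and_close(areas, registry)
    values, states = assign_states(closed, [s.id for s in registry], trace_cutoff=trace_cutoff)
    return CompositionProfile(strain=strain, values=values, states=states)


def aggregate_replicates(profiles: Sequence[CompositionProfile]) -> pd.DataFrame:
    """Summarise >= 2 replicate profiles of one strain as mean +/- sd.

    TRACE replicates count as 0 toward the mean but the aggregate keeps the
    TRACE label when any replicate was TRACE; a species is ND only when ND
    in every replicate.  Returns a frame indexed by lipid id with columns
    ``mean_pct``, ``sd_pct`` (ddof=1) and ``state``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicate profiles")
    strains = {p.strain for p in profiles}
    if len(strains) != 1:
        raise ValueError(f"replicates mix strains: {sorted(strains)}")
    ids = sorted({lid for p in profiles for lid in p.states})
    rows = []
    for lid in ids:
        states = [p.states.get(lid, ND) for p in profiles]
        vals = np.array([p.value(lid) for p in profiles], dtype=float)
        if all(s == ND for s in states):
            state = ND
        elif any(s == TRACE for s in states):
            state = TRACE
        else:
            state = QUANT
        rows.append((lid, float(vals.mean()), float(vals.std(ddof=1)), state))
    return pd.DataFrame(rows, columns=["lipid_id", "mean_pct", "sd_pct", "state"]).set_index("lipid_id")
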