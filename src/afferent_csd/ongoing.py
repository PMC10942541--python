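"""Ongoing-activity quantification and post-CSD change classification.

Ongoing activity is the fraction of stillness time an afferent spends
inside fluorescence events, computed in 1-min bins (bins with under 50%
stillness coverage are marked missing).  An afferent is classified as
activated (suppressed) after CSD when its binned rate stays above
baseline mean + k*SD (below baseline mean - k*SD) for a run longer than
10 consecutive minutes that begins within 30 min of the wave offset.

The baseline-referenced +/- k*SD bin criterion is this package's
operationalization of a "sustained change"; ``k_sd`` is configurable.  When
the lower threshold clips at zero (sparse baselines), bins with exactly
zero occupancy count as reduced, so complete silence remains detectable.
Missing bins (locomotion gaps) never break a run — they carry no evidence
— and short stretches of sub-criterion measured bins are bridged, provided
the run keeps a majority (60%) of its measured bins qualifying.  The
bridging is a power consideration: with clustered events, a genuinely
elevated bin clears a +2SD threshold only ~3 times in 4, so an unbridged
consecutive-bin rule would miss many sustained changes, while a spurious
run still needs a majority of >2SD bins and so remains vanishingly rare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import EventTrain

__all__ = ["OngoingActivityProfile", "bin_ongoing_rate", "classify_ongoing_change"]


@dataclass
class OngoingActivityProfile:
    bin_rate: np.ndarray      # per-1-min event occupancy; NaN = missing
    bin_coverage: np.ndarray  # stillness fraction of each bin
    baseline_mean: float
    baseline_sd: float
    classification: str       # "activated" | "suppressed" | "none"
    onset_latency_min: float | None
    duration_min: float | None


def bin_ongoing_rate(
    events: EventTrain,
    stillness_mask: np.ndarray,
    frame_rate_hz: float,
    bin_min: float = 1.0,
    min_coverage: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin event occupancy during stillness.

    Returns ``(rates, coverage)``: for each full ``bin_min``-minute bin, the
    fraction of stillness frames inside events and the stillness fraction
    of the bin.  Bins with coverage below ``min_coverage`` have NaN rate; a
    trailing partial bin is dropped.
    """
    still = np.asarray(stillness_mask, dtype=bool)
    ind = events.indicator()
    if len(ind) != len(still):
        raise ValueError("stillness mask must align with the event frame base")
    bin_frames = int(round(bin_min * 60 * frame_rate_hz))
    n_bins = len(still) // bin_frames
    rates = np.full(n_bins, np.nan)
    coverage = np.zeros(n_bins)
    for b in range(n_bins):
        sl = slice(b * bin_frames, (b + 1) * bin_frames)
        s = still[sl]
        coverage[b] = s.mean()
        if coverage[b] >= min_coverage and s.any():
            rates[b] = float(ind[sl][s].mean())
    return rates, coverage


def _qualifying_runs(qual: np.ndarray, missing: np.ndarray,
                     max_bridge: int = 3, missing_cap: int = 10,
                     min_qual_frac: float = 0.6):
    """Sustained runs of qualifying bins.

    A run extends from a qualifying bin through later qualifying bins.
    Missing bins carry no evidence: they never break a run (up to
    ``missing_cap`` consecutive).  Measured (non-missing) bins that fail
    the criterion are bridged up to ``max_bridge`` in a row.  Runs keeping
    fewer than ``min_qual_frac`` of their measured bins qualifying are
    discarded.  Returns (start_bin, end_bin_inclusive) pairs.
    """
    n = len(qual)
    runs = []
    i = 0
    while i < n:
        if not qual[i]:
            i += 1
            continue
        start = end = i
        j = i + 1
        bad = miss = 0
        while j < n:
            if qual[j]:
                end = j
                bad = miss = 0
            elif missing[j]:
                miss += 1
                if miss > missing_cap:
                    break
            else:
                bad += 1
                miss = 0
                if bad > max_bridge:
                    break
            j += 1
        span = slice(start, end + 1)
        measured = int((~missing[span]).sum())
        if measured > 0 and qual[span].sum() >= min_qual_frac * measured:
            runs.append((start, end))
        i = max(j, end + 1)
    return runs


def classify_ongoing_change(
    rates: np.ndarray,
    coverage: np.ndarray,
    wave_onset_min: float,
    wave_offset_min: float,
    k_sd: float = 2.0,
    run_min: float = 10.0,
    onset_window_min: float = 30.0,
    min_baseline_bins: int = 15,
    max_missing_bridge: int = 3,
    missing_cap: int = 10,
    min_qual_frac: float = 0.6,
    bin_min: float = 1.0,
) -> OngoingActivityProfile:
    """Classify a post-CSD afferent as activated, suppressed or unchanged.

    Baseline statistics come from the non-missing bins that end before the
    wave onset.  Post-CSD bins start at the first full bin after the wave
    offset.  A change must last more than ``run_min`` consecutive minutes
    and begin within ``onset_window_min`` of the wave offset; see
    :func:`_qualifying_runs` for how locomotion-induced missing bins and
    isolated sub-criterion bins are bridged.
    """
    rates = np.asarray(rates, dtype=float)
    missing = ~np.isfinite(rates)
    base_end = int(np.floor(wave_onset_min / bin_min))
    base = rates[:base_end]
    base = base[np.isfinite(base)]
    if len(base) < min_baseline_bins:
        raise ValueError(
            f"only {len(base)} usable baseline bins; need >= {min_baseline_bins}"
        )
    mean, sd = float(base.mean()), float(base.std())
    post_start = int(np.ceil(wave_offset_min / bin_min))
    up_thr = mean + k_sd * sd
    lo_thr = max(0.0, mean - k_sd * sd)
    finite = np.isfinite(rates)
    elevated = finite & (rates > up_thr)
    if lo_thr > 0:
        reduced = finite & (rates <= lo_thr) & (rates < mean)
    else:
        reduced = finite & (rates == 0.0) & (mean > 0)
    elevated[:post_start] = False
    reduced[:post_start] = False

    def _best_run(qual, bridge):
        for start, end in _qualifying_runs(qual, missing, bridge,
                                           missing_cap, min_qual_frac):
            span = (end - start + 1) * bin_min
            latency = start * bin_min - wave_offset_min
            if span > run_min and latency <= onset_window_min:
                return max(latency, 0.0), span
        return None

    act = _best_run(elevated, max_missing_bridge)
    # the degenerate silence criterion (threshold clipped at zero) reads
    # "complete silence": any measured non-zero bin ends the run
    sup = _best_run(reduced, max_missing_bridge if lo_thr > 0 else 0)
    if act is not None and (sup is None or act[0] <= sup[0]):
        cls, (lat, dur) = "activated", act
    elif sup is not None:
        cls, (lat, dur) = "suppressed", sup
    else:
        cls, lat, dur = "none", None, None
    return OngoingActivityProfile(
        bin_rate=rates,
        bin_coverage=np.asarray(coverage, dtype=float),
        baseline_mean=mean,
        baseline_sd=sd,
        classification=cls,
        onset_latency_min=lat,
        duration_min=dur,
    )
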