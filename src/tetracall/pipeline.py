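"""Per-marker orchestration: pre-filtering, model selection and genotype calls.

For each marker the pipeline

1. drops observations below the total-intensity threshold and rejects the
   marker if too few samples remain;
2. fits 16 mixture variants (4 mean models x {free, HWE} proportions x
   2 start configurations) by EM;
3. selects the minimum-BIC fit provisionally and tests it for a gap misfit
   (the simplex or triplex component stranded in a wide empty interval when
   the channel sensitivities are very unequal); if detected, refits the
   8 variants from a rescue start configuration;
4. removes fits showing a valley pattern (a lower-frequency genotype class
   between two higher ones, not expected in a cross progeny or an HWE
   population) unless every fit shows one or the check is disabled;
5. selects the final minimum-BIC fit, assigns a dosage to every sample whose
   maximum posterior exceeds the calling threshold, and applies the
   marker-level quality filters (call fraction, component SD, largest-peak
   share).

Every rejected marker carries exactly one reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .em import (
    FitFailure,
    MixtureFit,
    fit_mixture,
    start_means_clustering,
    start_means_equidistant,
)
from .model import asr_transform

MISSING = -1

#: Rejection reason codes, in the order the checks run.
REASONS = (
    "low_intensity_coverage",
    "all_fits_failed",
    "low_call_fraction",
    "sigma_too_high",
    "one_peak_dominant",
)

MIN_USABLE_SAMPLES = 10


@dataclass
class CallingOptions:
    """Thresholds controlling marker filtering, model selection and calling.

    intensity_threshold
        Minimum Euclidean total raw intensity for an observation to be used
        (GoldenGate-specific; ignored for ratio-only input).
    call_prob_threshold
        Minimum maximum-posterior probability for a sample to be assigned a
        dosage.
    min_call_fraction
        Minimum fraction of used samples that must receive a call.
    max_sigma
        Maximum admissible component SD on the transformed scale.
    max_peak_fraction
        Maximum share of assigned samples allowed in a single dosage class.
    valley_check_enabled
        Whether to reject fits with a lower peak between higher peaks.
    min_samples_above_threshold_fraction
        Minimum fraction of samples that must pass the intensity filter.
    """

    intensity_threshold: float = 3200.0
    call_prob_threshold: float = 0.99
    min_call_fraction: float = 0.60
    max_sigma: float = 0.1
    max_peak_fraction: float = 0.85
    valley_check_enabled: bool = True
    min_samples_above_threshold_fraction: float = 0.60

    def __post_init__(self):
        for name in (
            "call_prob_threshold",
            "min_call_fraction",
            "max_peak_fraction",
            "min_samples_above_threshold_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.intensity_threshold <= 0 or self.max_sigma <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class MarkerResult:
    """Outcome of calling one marker."""

    marker_id: str
    status: str  # "called" | "rejected"
    rejection_reason: str | None
    selected_fit: MixtureFit | None
    calls: np.ndarray | None  # per used sample; MISSING where unassigned
    sample_ids: list[str]  # samples that passed the intensity filter
    ratios: np.ndarray | None  # their signal ratios
    excluded_sample_ids: list[str]  # samples dropped by the intensity filter
    n_used: int
    call_fraction: float
    peak_fractions: np.ndarray
    rescue_applied: bool
    candidate_bics: pd.DataFrame
    n_fit_failures: int = 0


def intensity_prefilter(marker_df: pd.DataFrame, options: CallingOptions):
    """Drop low-intensity observations; decide whether the marker is usable.

    ``marker_df`` holds one marker's rows with at least ``sample_id`` and
    ``ratio`` columns and optionally ``intensity``.  Returns
    ``(retained_df, passed)``: the marker fails when fewer than
    ``min_samples_above_threshold_fraction`` of its samples reach the
    intensity threshold, or fewer than 10 usable samples remain.  Ratio-only
    input (no intensity column, or all-NaN) skips the intensity test.
    """
    df = marker_df.dropna(subset=["ratio"])
    n_total = len(marker_df)
    if "intensity" in df.columns and df["intensity"].notna().any():
        df = df[df["intensity"] >= options.intensity_threshold]
    if n_total == 0:
        return df, False
    frac = len(df) / n_total
    passed = frac >= options.min_samples_above_threshold_fraction and len(df) >= MIN_USABLE_SAMPLES
    return df, passed


# The 8 variants, in tie-break order: model id ascending, HWE before free.
VARIANTS = [(m, hwe) for m in (1, 2, 3, 4) for hwe in (True, False)]


def fit_all_variants(
    y: np.ndarray,
    start_sets: Iterable[tuple[str, np.ndarray]],
) -> tuple[list[MixtureFit], int]:
    """Fit every mixture variant from every start configuration.

    Individual numerical failures are counted, never fatal; returns the
    completed fits and the failure count.
    """
    fits: list[MixtureFit] = []
    n_fail = 0
    for label, means in start_sets:
        for model_id, hwe in VARIANTS:
            try:
                fits.append(
                    fit_mixture(y, model_id, hwe, means, start_label=label)
                )
            except FitFailure:
                n_fail += 1
    return fits, n_fail


def assign_genotypes(posteriors: np.ndarray, call_prob_threshold: float) -> np.ndarray:
    """Per-sample dosage call: argmax class if its posterior exceeds the
    threshold, else MISSING."""
    post = np.asarray(posteriors, dtype=float)
    best = post.argmax(axis=1)
    return np.where(post.max(axis=1) > call_prob_threshold, best, MISSING)


def _assigned_counts(calls: np.ndarray) -> np.ndarray:
    return np.bincount(calls[calls != MISSING], minlength=5)


def detect_gap_misfit(fit: MixtureFit, calls: np.ndarray) -> str | None:
    """Detect the simplex or triplex component fitted into an empty gap.

    Flags ``triplex_in_gap`` when the dosage-3 component has a lower mixing
    proportion, or fewer assigned samples, than the components on both
    sides; analogously ``simplex_in_gap`` for dosage 1.  The triplex side
    is tested first.
    """
    counts = _assigned_counts(calls)

    def in_gap(j: int) -> bool:
        lower_pi = fit.pi[j] < fit.pi[j - 1] and fit.pi[j] < fit.pi[j + 1]
        lower_n = counts[j] < counts[j - 1] and counts[j] < counts[j + 1]
        return lower_pi or lower_n

    if in_gap(3):
        return "triplex_in_gap"
    if in_gap(1):
        return "simplex_in_gap"
    return None


def rescue_start_means(mu: np.ndarray, which_gap: str) -> np.ndarray:
    """Rearranged start means used to refit after a detected gap misfit.

    Triplex in gap: the duplex, simplex and nulliplex means move up to the
    triplex, duplex and simplex slots and the new nulliplex mean is placed
    halfway between the new simplex mean and 0.  Simplex in gap: the mirror
    construction toward pi/2.
    """
    m = np.asarray(mu, dtype=float)
    if which_gap == "triplex_in_gap":
        return np.array([m[0] / 2.0, m[0], m[1], m[2], m[4]])
    if which_gap == "simplex_in_gap":
        return np.array([m[0], m[2], m[3], m[4], (m[4] + np.pi / 2.0) / 2.0])
    raise ValueError(f"unknown gap type {which_gap!r}")


def _valley_flag(counts: np.ndarray) -> bool:
    """True when some interior class has fewer assigned samples than at
    least one class on each side."""
    for j in (1, 2, 3):
        if counts[:j].max() > counts[j] and counts[j + 1 :].max() > counts[j]:
            return True
    return False


def reject_valley_fits(
    fits: list[MixtureFit],
    call_prob_threshold: float,
    enabled: bool = True,
) -> list[MixtureFit]:
    """Remove fits whose assigned-sample counts show a valley pattern.

    If every fit is flagged, or the check is disabled, no fit is removed.
    """
    if not enabled or not fits:
        return fits
    keep = [
        f
        for f in fits
        if not _valley_flag(
            _assigned_counts(assign_genotypes(f.posteriors, call_prob_threshold))
        )
    ]
    return keep if keep else fits


def _fit_sort_key(order: dict[int, int]):
    def key(fit: MixtureFit):
        return (fit.bic, fit.model_id, 0 if fit.hwe_constrained else 1, order[id(fit)])

    return key


def _select_min_bic(fits: list[MixtureFit], order: dict[int, int]) -> MixtureFit:
    return min(fits, key=_fit_sort_key(order))


def _candidate_table(fits: list[MixtureFit], selected: MixtureFit | None) -> pd.DataFrame:
    rows = [
        {
            "model": f.model_id,
            "hwe": f.hwe_constrained,
            "start": f.start_label,
            "loglik": f.loglik,
            "bic": f.bic,
            "converged": f.converged,
            "selected": f is selected,
        }
        for f in fits
    ]
    return pd.DataFrame(
        rows, columns=["model", "hwe", "start", "loglik", "bic", "converged", "selected"]
    )


def _rejected(
    marker_id: str,
    reason: str,
    *,
    sample_ids: list[str] | None = None,
    ratios: np.ndarray | None = None,
    excluded: list[str] | None = None,
    n_used: int = 0,
    fits: list[MixtureFit] | None = None,
    selected: MixtureFit | None = None,
    calls: np.ndarray | None = None,
    call_fraction: float = 0.0,
    peak_fractions: np.ndarray | None = None,
    rescue: bool = False,
    n_fail: int = 0,
) -> MarkerResult:
    return MarkerResult(
        marker_id=marker_id,
        status="rejected",
        rejection_reason=reason,
        selected_fit=selected,
        calls=calls,
        sample_ids=sample_ids or [],
        ratios=ratios,
        excluded_sample_ids=excluded or [],
        n_used=n_used,
        call_fraction=call_fraction,
        peak_fractions=peak_fractions if peak_fractions is not None else np.zeros(5),
        rescue_applied=rescue,
        candidate_bics=_candidate_table(fits or [], selected),
        n_fit_failures=n_fail,
    )


def call_marker(marker_df: pd.DataFrame, options: CallingOptions | None = None) -> MarkerResult:
    """Run the full per-marker procedure and return a MarkerResult.

    ``marker_df`` holds one marker's observations with columns
    ``sample_id``, ``ratio`` and optionally ``intensity``.  Never raises on
    a fittable-but-poor marker: quality problems become rejection statuses.
    """
    options = options or CallingOptions()
    marker_id = str(marker_df["marker_id"].iloc[0]) if "marker_id" in marker_df else ""

    retained, passed = intensity_prefilter(marker_df, options)
    excluded = sorted(set(marker_df["sample_id"]) - set(retained["sample_id"]))
    if not passed:
        return _rejected(marker_id, "low_intensity_coverage", excluded=excluded)

    retained = retained.sort_values("sample_id", kind="stable")
    sample_ids = retained["sample_id"].tolist()
    ratios = retained["ratio"].to_numpy(dtype=float)
    y = asr_transform(ratios)

    cluster_means = start_means_clustering(y)
    if np.ptp(cluster_means) < 1e-12:
        cluster_means = start_means_equidistant()
    start_sets = [("clustering", cluster_means), ("equidistant", start_means_equidistant())]
    fits, n_fail = fit_all_variants(y, start_sets)
    if not fits:
        return _rejected(
            marker_id, "all_fits_failed",
            sample_ids=sample_ids, ratios=ratios, excluded=excluded,
            n_used=len(y), n_fail=n_fail,
        )
    order = {id(f): i for i, f in enumerate(fits)}

    provisional = _select_min_bic(fits, order)
    prov_calls = assign_genotypes(provisional.posteriors, options.call_prob_threshold)
    gap = detect_gap_misfit(provisional, prov_calls)
    rescue = gap is not None
    if rescue:
        rescue_fits, extra_fail = fit_all_variants(
            y, [("rescue", rescue_start_means(provisional.mu, gap))]
        )
        n_fail += extra_fail
        fits = fits + rescue_fits
        order = {id(f): i for i, f in enumerate(fits)}

    survivors = reject_valley_fits(
        fits, options.call_prob_threshold, options.valley_check_enabled
    )
    final = _select_min_bic(survivors, order)
    calls = assign_genotypes(final.posteriors, options.call_prob_threshold)
    n_used = len(y)
    n_assigned = int((calls != MISSING).sum())
    call_fraction = n_assigned / n_used
    counts = _assigned_counts(calls)
    peak_fractions = counts / n_assigned if n_assigned else np.zeros(5)

    reason = None
    if call_fraction < options.min_call_fraction:
        reason = "low_call_fraction"
    elif final.sigma > options.max_sigma:
        reason = "sigma_too_high"
    elif peak_fractions.max() > options.max_peak_fraction:
        reason = "one_peak_dominant"

    if reason is not None:
        return _rejected(
            marker_id, reason,
            sample_ids=sample_ids, ratios=ratios, excluded=excluded,
            n_used=n_used, fits=fits, selected=final, calls=calls,
            call_fraction=call_fraction, peak_fractions=peak_fractions,
            rescue=rescue, n_fail=n_fail,
        )
    return MarkerResult(
        marker_id=marker_id,
        status="called",
        rejection_reason=None,
        selected_fit=final,
        calls=calls,
        sample_ids=sample_ids,
        ratios=ratios,
        excluded_sample_ids=excluded,
        n_used=n_used,
        call_fraction=call_fraction,
        peak_fractions=peak_fractions,
        rescue_applied=rescue,
        candidate_bics=_candidate_table(fits, final),
        n_fit_failures=n_fail,
    )


def call_panel(
    data: pd.DataFrame,
    options: CallingOptions | None = None,
    markers: Iterable[str] | None = None,
) -> list[MarkerResult]:
    """Call every marker in a long-format table independently.

    Markers are processed in sorted order; results do not depend on the
    input row order.
    """
    options = options or CallingOptions()
    wanted = set(markers) if markers is not None else None
    results = []
    for marker_id in sorted(data["marker_id"].unique()):
        if wanted is not None and marker_id not in wanted:
            continue
        results.append(call_marker(data[data["marker_id"] == marker_id], options))
    return results
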