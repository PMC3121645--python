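"""Reading assay exports and writing the tabular outputs.

Input is a delimited long-format text file with one row per marker x sample.
Raw mode expects two channel-intensity columns (GoldenGate default names
``Raw_X``/``Raw_Y`` with ``SNP_Name``/``Sample_ID``); ratio mode expects a
precomputed signal-ratio column instead.  Column names are remappable and
the delimiter is auto-detected among comma, tab and semicolon.

Outputs are two tab-separated tables: one row per marker describing the
selected model (or the rejection reason), and one row per marker x sample
with the five posterior dosage probabilities and the assigned genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import asr_inverse, compute_ratio_and_intensity
from .pipeline import MISSING, MarkerResult

logger = logging.getLogger("tetracall")

#: GoldenGate-export default column names.
DEFAULT_COLUMNS = {
    "marker": "SNP_Name",
    "sample": "Sample_ID",
    "x": "Raw_X",
    "y": "Raw_Y",
    "ratio": "ratio",
}


class AssayFormatError(ValueError):
    """The input file does not match the expected dialect."""


@dataclass
class AssayTable:
    """Typed long-format assay data plus the sample ploidy split.

    ``data`` holds one row per valid (marker, sample) observation with
    columns ``marker_id, sample_id, ratio`` and, in raw mode,
    ``s_a, s_b, intensity``.  ``diploid_samples`` are overlay-only and are
    excluded from ``fitting_data``.
    """

    data: pd.DataFrame
    mode: str  # "raw" | "ratio"
    n_bad_rows: int = 0
    diploid_samples: set = field(default_factory=set)

    @property
    def fitting_data(self) -> pd.DataFrame:
        if not self.diploid_samples:
            return self.data
        return self.data[~self.data["sample_id"].isin(self.diploid_samples)]

    @property
    def diploid_data(self) -> pd.DataFrame:
        return self.data[self.data["sample_id"].isin(self.diploid_samples)]


def _detect_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    counts = {sep: header.count(sep) for sep in (",", "\t", ";")}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise AssayFormatError("could not detect a delimiter (comma/tab/semicolon)")
    return best


def read_roster(path) -> dict[str, int]:
    """Read a two-column (sample, ploidy) roster file; ploidy 2 or 4."""
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise AssayFormatError("roster needs two columns: sample, ploidy")
    out = {}
    for _, row in df.iterrows():
        raw = str(row.iloc[1]).strip().lower()
        ploidy = {"2": 2, "diploid": 2, "4": 4, "tetraploid": 4}.get(raw)
        if ploidy is None:
            raise AssayFormatError(f"unrecognized ploidy {row.iloc[1]!r} in roster")
        out[str(row.iloc[0])] = ploidy
    return out


def read_assay(
    path,
    columns: dict[str, str] | None = None,
    ratio_mode: bool = False,
    roster: dict[str, int] | None = None,
    delimiter: str | None = None,
) -> AssayTable:
    """Read a delimited assay export into an AssayTable.

    Raw mode computes the signal ratio and the Euclidean total intensity on
    load; records with both channels zero, negative or non-numeric
    intensities are dropped, counted and logged, never silently.  Ratio
    mode accepts a precomputed ratio column and carries no intensity (the
    intensity pre-filter is skipped downstream, with a logged notice).

    Raises
    ------
    AssayFormatError
        When a required column is missing or (marker, sample) pairs repeat.
    """
    cols = dict(DEFAULT_COLUMNS)
    cols.update(columns or {})
    sep = delimiter or _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep)

    required = [cols["marker"], cols["sample"]] + (
        [cols["ratio"]] if ratio_mode else [cols["x"], cols["y"]]
    )
    for name in required:
        if name not in raw.columns:
            raise AssayFormatError(f"missing required column {name!r}")

    df = pd.DataFrame(
        {
            "marker_id": raw[cols["marker"]].astype(str),
            "sample_id": raw[cols["sample"]].astype(str),
        }
    )
    n_bad = 0
    if ratio_mode:
        ratio = pd.to_numeric(raw[cols["ratio"]], errors="coerce")
        bad = ratio.isna() | (ratio < 0) | (ratio > 1)
        n_bad = int(bad.sum())
        df["ratio"] = ratio
        df = df[~bad.to_numpy()]
        logger.info("ratio-mode input: intensity pre-filter will be skipped")
    else:
        s_a = pd.to_numeric(raw[cols["x"]], errors="coerce")
        s_b = pd.to_numeric(raw[cols["y"]], errors="coerce")
        bad = s_a.isna() | s_b.isna() | (s_a < 0) | (s_b < 0) | (s_a + s_b <= 0)
        n_bad = int(bad.sum())
        if n_bad:
            for line in (np.flatnonzero(bad.to_numpy()) + 2)[:10]:
                logger.warning("dropping unparseable/invalid row at line %d", line)
        df["s_a"] = s_a
        df["s_b"] = s_b
        df = df[~bad.to_numpy()]
        ratio, intensity = compute_ratio_and_intensity(
            df["s_a"].to_numpy(), df["s_b"].to_numpy()
        )
        df["ratio"] = ratio
        df["intensity"] = intensity
    if n_bad:
        logger.warning("dropped %d invalid rows", n_bad)

    dup = df.duplicated(subset=["marker_id", "sample_id"])
    if dup.any():
        pair = df[dup].iloc[0]
        raise AssayFormatError(
            f"duplicate (marker, sample) pair: ({pair['marker_id']}, {pair['sample_id']})"
        )

    diploids: set = set()
    if roster:
        diploids = {s for s, pl in roster.items() if pl == 2}
        unknown = set(df["sample_id"]) - set(roster)
        if unknown:
            logger.warning(
                "%d samples absent from roster; treated as tetraploid", len(unknown)
            )
    return AssayTable(
        data=df.reset_index(drop=True),
        mode="ratio" if ratio_mode else "raw",
        n_bad_rows=n_bad,
        diploid_samples=diploids,
    )


def write_assay(table_or_df, path) -> None:
    """Write a long-format assay table in the GoldenGate dialect (CSV)."""
    df = table_or_df.data if isinstance(table_or_df, AssayTable) else table_or_df
    out = pd.DataFrame(
        {
            "SNP_Name": df["marker_id"],
            "Sample_ID": df["sample_id"],
            "Raw_X": df["s_a"],
            "Raw_Y": df["s_b"],
        }
    )
    out.to_csv(path, index=False)


def model_table(results: list[MarkerResult]) -> pd.DataFrame:
    """One row per marker describing the selected model or the rejection."""
    rows = []
    for res in results:
        row = {
            "marker": res.marker_id,
            "status": res.status,
            "reason": res.rejection_reason or "",
            "n_used": res.n_used,
            "call_fraction": round(res.call_fraction, 6),
            "rescue_applied": res.rescue_applied,
        }
        fit = res.selected_fit
        if fit is not None:
            back = asr_inverse(fit.mu)
            row.update(
                {
                    "model": fit.model_id,
                    "hwe": fit.hwe_constrained,
                    "c1": fit.params.c1,
                    "c2": fit.params.c2,
                    "r": fit.params.r,
                    "d": fit.params.d,
                    **{f"mu{j}": fit.mu[j] for j in range(5)},
                    **{f"ratio_mu{j}": back[j] for j in range(5)},
                    "sigma": fit.sigma,
                    **{f"pi{j}": fit.pi[j] for j in range(5)},
                    "p": fit.p if fit.p is not None else "",
                    "p_allele_a": fit.p_allele_a if fit.p is not None else "",
                    "loglik": fit.loglik,
                    "k": fit.k,
                    "bic": fit.bic,
                }
            )
        rows.append(row)
    cols = [
        "marker", "status", "reason", "model", "hwe",
        "c1", "c2", "r", "d",
        *[f"mu{j}" for j in range(5)], *[f"ratio_mu{j}" for j in range(5)],
        "sigma", *[f"pi{j}" for j in range(5)], "p", "p_allele_a",
        "loglik", "k", "bic", "n_used", "call_fraction", "rescue_applied",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)


def write_model_table(results: list[MarkerResult], path) -> None:
    model_table(results).to_csv(path, sep="\t", index=False)


def score_table(results: list[MarkerResult]) -> pd.DataFrame:
    """One row per marker x sample with posteriors and the assigned dosage.

    The genotype column holds the allele-a dosage 0..4 and is empty for
    unassigned samples; samples excluded by the intensity pre-filter appear
    with empty posteriors.
    """
    frames = []
    for res in results:
        if res.selected_fit is not None and res.calls is not None:
            post = res.selected_fit.posteriors
            df = pd.DataFrame(
                {
                    "marker": res.marker_id,
                    "sample": res.sample_ids,
                    "ratio": np.round(res.ratios, 6),
                    **{f"P{j}": np.round(post[:, j], 6) for j in range(5)},
                    "maxP": np.round(post.max(axis=1), 6),
                    "geno": [
                        "" if c == MISSING else str(int(c)) for c in res.calls
                    ],
                }
            )
            frames.append(df)
        if res.excluded_sample_ids:
            frames.append(
                pd.DataFrame(
                    {
                        "marker": res.marker_id,
                        "sample": res.excluded_sample_ids,
                        "geno": "",
                    }
                )
            )
    cols = ["marker", "sample", "ratio", *[f"P{j}" for j in range(5)], "maxP", "geno"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True).reindex(columns=cols)


def write_score_table(results: list[MarkerResult], path) -> None:
    score_table(results).to_csv(path, sep="\t", index=False)


def run_summary(results: list[MarkerResult]) -> dict:
    """Counts per outcome over a panel; reasons plus 'called' sum to the
    number of markers."""
    summary = {"n_markers": len(results), "called": 0}
    for reason in (
        "low_intensity_coverage",
        "all_fits_failed",
        "low_call_fraction",
        "sigma_too_high",
        "one_peak_dominant",
    ):
        summary[reason] = 0
    for res in results:
        if res.status == "called":
            summary["called"] += 1
        else:
            summary[res.rejection_reason] += 1
    return summary
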