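"""Synthetic two-channel assay data with known ground truth.

Emulates the signal structure the calling model assumes: each sample's true
allele-a dosage is drawn from the mixing proportions, its expected
transformed ratio follows one of the four dosage->mean models, and Gaussian
noise is added either on the transformed scale (matching the fitted model
exactly) or multiplicatively on the raw channel signals (probing the
transform approximations).  Raw channel intensities are then emitted in the
same long-format dialect the reader consumes, together with a truth table.

Failure-mode switches plant the pathologies the marker filters exist for:
monomorphic markers, diffuse (high-noise) markers, and wide-gap markers with
strongly unequal channel sensitivities where EM is prone to stranding the
simplex or triplex component in the empty interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    DOSAGES,
    MeanModelParams,
    asr_inverse,
    compute_ratio_and_intensity,
    hwe_proportions,
    mean_model_eval,
)

FAILURE_MODES = ("none", "monomorphic", "diffuse", "wide_gap")

#: Noise SD on the transformed scale used for "diffuse" markers; far above
#: the 0.1 marker-rejection cap so the planted failure is unambiguous.
DIFFUSE_SIGMA = 0.25

#: Wide-gap failure mode: sensitivity ratio 5 pushes the quadruplex peak far
#: from the four closely spaced lower peaks, and a high a-allele frequency
#: (b-allele frequency 0.1) leaves the low-dosage classes nearly empty —
#: the regime in which EM strands a component in the gap.  The noise level
#: is that of a well-performing assay (tight peaks): the marker's only
#: pathology is the unequal channel sensitivity.
WIDE_GAP_PARAMS = MeanModelParams(1, c1=0.02, c2=0.02, r=5.0)
WIDE_GAP_P = 0.1
WIDE_GAP_SIGMA = 0.03


@dataclass
class SimulationConfig:
    """Ground-truth settings for one simulated marker.

    Defaults mirror a well-behaved GoldenGate-style marker scored on a
    224-sample panel: symmetric channels with a small common background,
    per-class noise SD 0.04 on the transformed scale, mean total intensity
    8000 well above the 3200 filter threshold.
    """

    marker_id: str = "simSNP"
    n_samples: int = 224
    model_id: int = 2
    params: MeanModelParams | None = None
    pi_mode: str = "hwe"  # "hwe" | "explicit"
    p: float = 0.5  # b-allele frequency when pi_mode == "hwe"
    pi: np.ndarray | None = None  # explicit mixing proportions
    sigma: float = 0.04
    noise_mode: str = "transformed"  # "transformed" | "raw"
    intensity_scale: float = 8000.0
    intensity_cv: float = 0.3
    low_intensity_fraction: float = 0.0
    low_intensity_ceiling: float = 3200.0
    failure_mode: str = "none"
    seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Apply the failure-mode switches and fill in default parameters."""
        cfg = self
        if cfg.params is None:
            default = MeanModelParams.from_vector(
                cfg.model_id,
                {1: [0.02, 0.02, 1.0], 2: [0.02, 1.0], 3: [0.02, 0.02, 1.0, 0.0], 4: [0.02, 1.0, 0.0]}[
                    cfg.model_id
                ],
            )
            cfg = replace(cfg, params=default)
        if cfg.failure_mode == "monomorphic":
            # All samples share one boundary class; additive noise on the
            # transformed scale would clip at pi/2, so noise acts on the raw
            # channels (sigma = per-channel CV), as in a real assay.
            cfg = replace(cfg, noise_mode="raw")
        elif cfg.failure_mode == "diffuse":
            cfg = replace(cfg, sigma=DIFFUSE_SIGMA)
        elif cfg.failure_mode == "wide_gap":
            cfg = replace(cfg, model_id=1, params=WIDE_GAP_PARAMS, pi_mode="hwe",
                          p=WIDE_GAP_P, sigma=WIDE_GAP_SIGMA)
        elif cfg.failure_mode not in FAILURE_MODES:
            raise ValueError(f"unknown failure_mode {cfg.failure_mode!r}")
        return cfg

    def mixing_proportions(self) -> np.ndarray:
        if self.failure_mode == "monomorphic":
            pi = np.zeros(5)
            pi[4] = 1.0
            return pi
        if self.pi_mode == "hwe":
            return hwe_proportions(self.p)
        if self.pi_mode == "explicit":
            pi = np.asarray(self.pi, dtype=float)
            if pi.shape != (5,) or abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
                raise ValueError("explicit pi must be a 5-vector summing to 1")
            return pi
        raise ValueError(f"unknown pi_mode {self.pi_mode!r}")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and coefficient of variation."""
    s2 = np.log1p(cv**2)
    return rng.lognormal(np.log(mean) - 0.5 * s2, np.sqrt(s2), size)


def simulate_marker(config: SimulationConfig):
    """Simulate one marker's records.

    Returns ``(records, dosages, truth)``: a DataFrame with columns
    ``marker_id, sample_id, s_a, s_b, ratio, intensity``, the true dosage
    per sample, and a dict of the generating parameters.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    pi = cfg.mixing_proportions()
    n = cfg.n_samples
    dosages = rng.choice(5, size=n, p=pi)
    mu = mean_model_eval(cfg.params, DOSAGES)

    if cfg.noise_mode == "transformed":
        y = np.clip(mu[dosages] + rng.normal(0.0, cfg.sigma, n) if cfg.sigma > 0 else mu[dosages],
                    0.0, np.pi / 2.0)
        ratio = asr_inverse(y)
        total = _lognormal(rng, cfg.intensity_scale, cfg.intensity_cv, n)
        s_a = ratio * total
        s_b = (1.0 - ratio) * total
    elif cfg.noise_mode == "raw":
        prm = cfg.params
        x = dosages.astype(float)
        xb = 4.0 - x
        mean_a = prm.c1 + x + prm.d * x**2
        mean_b = prm.c2 + prm.r * xb + prm.r * prm.d * xb**2
        # Scale so that the mean total over dosage classes is intensity_scale;
        # sigma acts as the per-channel multiplicative coefficient of variation.
        a1 = cfg.intensity_scale / float((mean_a + mean_b).mean())
        cv = max(cfg.sigma, 1e-6)
        s_a = a1 * mean_a * _lognormal(rng, 1.0, cv, n)
        s_b = a1 * mean_b * _lognormal(rng, 1.0, cv, n)
    else:
        raise ValueError(f"unknown noise_mode {cfg.noise_mode!r}")

    if cfg.low_intensity_fraction > 0.0:
        n_low = int(round(cfg.low_intensity_fraction * n))
        idx = rng.choice(n, size=n_low, replace=False)
        current = np.hypot(s_a[idx], s_b[idx])
        target = rng.uniform(0.1, 0.9, n_low) * cfg.low_intensity_ceiling
        factor = np.where(current > 0, target / np.where(current > 0, current, 1.0), 0.0)
        s_a[idx] *= factor
        s_b[idx] *= factor

    ratio, intensity = compute_ratio_and_intensity(s_a, s_b)
    records = pd.DataFrame(
        {
            "marker_id": cfg.marker_id,
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "s_a": s_a,
            "s_b": s_b,
            "ratio": ratio,
            "intensity": intensity,
        }
    )
    truth = {
        "marker_id": cfg.marker_id,
        "model_id": cfg.params.model_id,
        "c1": cfg.params.c1,
        "c2": cfg.params.c2,
        "r": cfg.params.r,
        "d": cfg.params.d,
        "sigma": cfg.sigma,
        "pi": pi,
        "p": cfg.p if cfg.pi_mode == "hwe" and cfg.failure_mode != "monomorphic" else None,
        "failure_mode": cfg.failure_mode,
    }
    return records, dosages, truth


def simulate_panel(configs, seed: int | None = None):
    """Simulate a multi-marker panel in the long input dialect.

    Per-marker seeds are spawned deterministically from ``seed`` when given
    (otherwise each config's own seed is used).  Returns ``(data, truth)``:
    the assay table with columns ``marker_id, sample_id, s_a, s_b`` and a
    truth table with one row per marker x sample holding the true dosage.
    """
    configs = list(configs)
    ids = [c.marker_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker ids in panel")
    if seed is not None:
        seeds = np.random.SeedSequence(seed).generate_state(len(configs)) % (2**31)
        configs = [replace(c, seed=int(s)) for c, s in zip(configs, seeds)]
    frames = []
    truths = []
    for cfg in configs:
        rec, dosages, truth = simulate_marker(cfg)
        frames.append(rec[["marker_id", "sample_id", "s_a", "s_b"]])
        truths.append(
            pd.DataFrame(
                {
                    "marker_id": cfg.marker_id,
                    "sample_id": rec["sample_id"],
                    "true_dosage": dosages,
                    "failure_mode": truth["failure_mode"],
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    truth_table = pd.concat(truths, ignore_index=True)
    return data, truth_table
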