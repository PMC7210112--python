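"""Synthetic data generation: feature cohorts, PPR samples, stimulus trains.

The generators emulate the *statistical shape* of the recorded cohort so
the population pipeline (clustering, ANOVA, PPR inversion) can be
exercised without the deposited dataset:

* per-cell (IFC, f_initial) feature pairs at 10 pA drawn from per-subtype
  Gaussians.  The subtype proportions follow the recorded cohort
  (non-adapting 20.6%, adapting 66.7% split into strong/mild, accelerating
  12.7%); the per-subtype centroids are surrogate values chosen to respect
  the observed ordering (strong < mild < non ~ 0 < accelerating in IFC),
  not published numbers.
* PPR samples per group as truncated normals in (0, 2].
* stimulus trains, regular (the in-vitro electrical stimulation) or
  Poisson.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "PPRSampleSpec",
    "generate_cohort",
    "generate_ppr_samples",
    "generate_stimulus_train",
    "DEFAULT_SUBTYPE_STATS",
]

#: surrogate per-subtype (mean, SD) of IFC [%] and f_initial [Hz] at 10 pA
DEFAULT_SUBTYPE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "strong_adapting": {"ifc": (-70.0, 7.0), "f_initial": (50.0, 5.0)},
    "mild_adapting": {"ifc": (-35.0, 7.0), "f_initial": (44.0, 5.0)},
    "non_adapting": {"ifc": (0.0, 7.0), "f_initial": (38.0, 5.0)},
    "accelerating": {"ifc": (90.0, 10.0), "f_initial": (30.0, 5.0)},
}

#: recorded cohort proportions; the adapting fraction is split between
#: strong (23) and mild (19) following the cluster sizes
DEFAULT_PROPORTIONS: dict[str, float] = {
    "strong_adapting": 0.667 * 23.0 / 42.0,
    "mild_adapting": 0.667 * 19.0 / 42.0,
    "non_adapting": 0.206,
    "accelerating": 0.127,
}


@dataclass(frozen=True)
class CohortSpec:
    n_cells: int = 63
    proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    subtype_stats: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_STATS))
    seed: int = 0

    def __post_init__(self):
        tot = sum(self.proportions.values())
        if not np.isclose(tot, 1.0, atol=1e-3):
            raise ValueError(f"subtype proportions must sum to 1 (got {tot})")
        for st, stats in self.subtype_stats.items():
            for key in ("ifc", "f_initial"):
                if stats[key][1] < 0:
                    raise ValueError(f"{st}/{key}: SD must be >= 0")


def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer subtype counts by the largest-remainder rule (ties broken by
    dict order)."""
    keys = list(proportions)
    exact = np.array([n * proportions[k] for k in keys])
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = n - int(base.sum())
    order = np.argsort(-rem, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-cell feature table with ground-truth subtype labels.

    Columns: cell_id, subtype, ifc (%), f_initial (Hz).
    """
    rng = np.random.default_rng(spec.seed)
    counts = largest_remainder_counts(spec.n_cells, spec.proportions)
    rows = []
    cid = 0
    for subtype, cnt in counts.items():
        mu_i, sd_i = spec.subtype_stats[subtype]["ifc"]
        mu_f, sd_f = spec.subtype_stats[subtype]["f_initial"]
        ifc = rng.normal(mu_i, sd_i, size=cnt)
        f0 = rng.normal(mu_f, sd_f, size=cnt)
        for k in range(cnt):
            rows.append(
                {
                    "cell_id": cid,
                    "subtype": subtype,
                    "ifc": float(ifc[k]),
                    "f_initial": float(max(f0[k], 1.0)),
                }
            )
            cid += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PPRSampleSpec:
    group: str = "strong_adapting"   # or "accelerating"
    mean: float = 0.88
    sd: float = 0.05
    n: int = 47
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def generate_ppr_samples(spec: PPRSampleSpec) -> np.ndarray:
    """Truncated-normal PPR draws in (0, 2] (resampling outside the range)."""
    rng = np.random.default_rng(spec.seed)
    out = np.empty(spec.n)
    filled = 0
    while filled < spec.n:
        draw = rng.normal(spec.mean, spec.sd, size=spec.n)
        ok = draw[(draw > 0) & (draw <= 2.0)]
        take = min(len(ok), spec.n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
        if spec.sd == 0:
            out[:] = spec.mean
            break
    return out


def generate_stimulus_train(
    rate: float,
    duration: float,
    mode: str = "regular",
    seed: int | None = None,
) -> np.ndarray:
    """Presynaptic spike times (ms) over [0, duration).

    Regular trains start at one full inter-spike interval (a 20 Hz, 1000 ms
    train has exactly 20 spikes at 50 ms spacing); Poisson trains draw
    exponential ISIs from the seeded generator.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if duration <= 0:
        return np.zeros(0)
    isi = 1e3 / rate
    if mode == "regular":
        n = int(np.floor(duration / isi + 1e-9))
        return (np.arange(n) + 1.0) * isi - isi / 2.0
    if mode == "poisson":
        rng = np.random.default_rng(seed)
        times = []
        t = rng.exponential(isi)
        while t < duration:
            times.append(t)
            t += rng.exponential(isi)
        return np.array(times)
    raise ValueError("mode must be 'regular' or 'poisson'")
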