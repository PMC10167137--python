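"""Synthetic visual-search experiments with the study's statistical structure.

The generator emulates a case-control feature-search study: two cohorts
(39 vision-impaired children, 82% of them with nystagmus, and 33 controls),
each performing 80 presentations (8 practice + 72 test) across the six
set-size x target conditions, with every condition appearing 8-15 times in
a session.  Reaction times are Ex-Gaussian with a location that depends on
group, set-size band, target and gender; trial-level correctness is
Bernoulli with probabilities depending on set size, target and age band.

The default Ex-Gaussian parameter map is *calibrated*, not copied: the
target node medians (seconds) for each group x set-band x target x gender
cell are fixed and the Ex-Gaussian ``mu`` is solved numerically so that the
implied distribution median equals the target.  Set sizes 16 and 24 share
parameters — the band structure, not the individual large set sizes, is
what differentiates performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .distributions import exgauss_median, exgauss_rvs
from .preprocessing import CSV_COLUMNS, SET_SIZES, TARGET_LEVELS

__all__ = [
    "SimConfig",
    "SimulatedExperiment",
    "default_median_map",
    "accuracy_map_default",
    "build_rt_parameter_map",
    "sample_schedule",
    "simulate_experiment",
]

CONDITIONS = [(s, t) for s in SET_SIZES for t in TARGET_LEVELS]
SCHEDULE_MIN, SCHEDULE_MAX = 8, 15
N_TEST = 72
N_PRACTICE = 8


def default_median_map() -> dict:
    """Target median reaction times (s) per group x set-band x target x gender.

    Set sizes 16 and 24 form one band.  Where the underlying study reports
    a single median for a coarser cell, both genders inherit it.
    """
    med = {}
    for gender in ("f", "m"):
        med[("c", "4", "p", gender)] = 0.91
        med[("c", "4", "ab", gender)] = 1.08
        med[("i", "4", "p", gender)] = 1.59
        med[("i", "4", "ab", gender)] = 1.59
        med[("c", "16-24", "ab", gender)] = 2.43
        med[("i", "16-24", "p", gender)] = 2.15
    med[("i", "16-24", "ab", "f")] = 4.37
    med[("i", "16-24", "ab", "m")] = 3.10
    med[("c", "16-24", "p", "m")] = 1.51
    med[("c", "16-24", "p", "f")] = 1.38
    return med


def accuracy_map_default(set_size: int, target: str, age: float) -> float:
    """Per-trial probability of a correct response.

    Set size 4 is easy regardless of target or age (0.97).  At set sizes
    16/24, target-present accuracy drops for the younger band (< 14 years:
    0.88 vs 0.98 for the older band — misses of a present target), while
    target-absent accuracy stays high (0.98) for all ages: the age effect
    lives in the target-present branch only, and the absent-minus-present
    gap in the dominant younger band is about 0.10.

    ========  =======  ========  ========
    set size  target   age < 14  age >= 14
    ========  =======  ========  ========
    4         either   0.97      0.97
    16 / 24   present  0.88      0.98
    16 / 24   absent   0.98      0.98
    ========  =======  ========  ========
    """
    if set_size == 4:
        return 0.97
    if target == "p":
        return 0.88 if age < 14 else 0.98
    return 0.98


def _band(set_size: int) -> str:
    return "4" if set_size == 4 else "16-24"


@dataclass
class SimConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_impaired: int = 39
    n_control: int = 33
    nystagmus_prevalence: float = 0.82
    male_prop_impaired: float = 0.56
    male_prop_control: float = 0.61
    # cohort ages: mean and SD (SD reconstructed as SEM * sqrt(n)),
    # truncated to the study's 5-18-year inclusion window
    age_mean_impaired: float = 11.6
    age_sd_impaired: float = 0.5 * 39 ** 0.5
    age_mean_control: float = 13.0
    age_sd_control: float = 0.5 * 33 ** 0.5
    age_bounds: tuple = (5.0, 18.0)
    # binocular acuity (LogMAR)
    acuity_mean_impaired: float = 0.63
    acuity_sd_impaired: float = 0.05 * 39 ** 0.5
    acuity_bounds_impaired: tuple = (0.2, 1.5)
    acuity_mean_control: float = 0.0
    acuity_sd_control: float = 0.05
    acuity_bounds_control: tuple = (-0.15, 0.2)
    # Ex-Gaussian shape relative to the cell median: sigma and nu scale
    # linearly with the target median (RT spread grows with slowness)
    sigma_frac: float = 0.12
    nu_frac: float = 0.35
    median_map: dict = field(default_factory=default_median_map)
    # optional couplings (off by default: the emulated models have none)
    acuity_rt_slope: float = 0.0      # added to mu per LogMAR above cohort mean
    participant_sd: float = 0.0       # participant-level random intercept on mu
    # per-trial P(correct) as a function of (set_size, target, age);
    # None selects accuracy_map_default
    accuracy_map: object = None
    seed: int = 0

    def validate(self):
        for p in (self.nystagmus_prevalence, self.male_prop_impaired,
                  self.male_prop_control):
            if not 0.0 <= p <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        for key, med in self.median_map.items():
            if med <= 0:
                raise ValueError(f"non-positive median for cell {key}")
        acc = self.accuracy_map or accuracy_map_default
        for s, t in CONDITIONS:
            for age in (10.0, 16.0):
                pr = acc(s, t, age)
                if not 0.0 <= pr <= 1.0:
                    raise ValueError("accuracy probabilities must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "median_map" in raw:
            raw["median_map"] = {tuple(k.split("|")): v
                                 for k, v in raw["median_map"].items()}
        return cls(**raw)

    def to_yaml(self, path):
        raw = asdict(self)
        raw.pop("accuracy_map", None)   # callables are not serialised
        raw["median_map"] = {"|".join(map(str, k)): float(v)
                             for k, v in self.median_map.items()}
        raw["age_bounds"] = list(self.age_bounds)
        raw["acuity_bounds_impaired"] = list(self.acuity_bounds_impaired)
        raw["acuity_bounds_control"] = list(self.acuity_bounds_control)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass
class SimulatedExperiment:
    trials: pd.DataFrame
    ground_truth: dict

    def to_csv(self, path):
        self.trials[CSV_COLUMNS].to_csv(path, index=False)

    def ground_truth_json(self) -> str:
        return json.dumps(self.ground_truth, sort_keys=True)


def build_rt_parameter_map(config: SimConfig) -> dict:
    """Solve the Ex-Gaussian parameters whose medians hit the calibration
    targets.

    For each cell, ``sigma = sigma_frac * m`` and ``nu = nu_frac * m`` with
    ``m`` the target median; ``mu`` is then ``m`` minus the median of the
    zero-location Ex-Gaussian, so the cell median equals ``m`` exactly.
    """
    out = {}
    for key, m in config.median_map.items():
        sigma = config.sigma_frac * m
        nu = config.nu_frac * m
        mu = m - exgauss_median(0.0, sigma, nu)
        out[key] = (float(mu), float(sigma), float(nu))
    return out


def sample_schedule(rng, max_tries: int = 100_000):
    """72 test-condition labels: iid-uniform draws over the six conditions,
    resampled until every condition count lies in [8, 15]."""
    for _ in range(max_tries):
        idx = rng.integers(0, len(CONDITIONS), size=N_TEST)
        counts = np.bincount(idx, minlength=len(CONDITIONS))
        if counts.min() >= SCHEDULE_MIN and counts.max() <= SCHEDULE_MAX:
            return [CONDITIONS[i] for i in idx]
    raise RuntimeError("schedule resampling did not terminate")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    for i in range(size):
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                out[i] = v
                break
        else:
            out[i] = float(np.clip(mean, lo, hi))
    return out


def _draw_participants(config: SimConfig, rng) -> pd.DataFrame:
    rows = []
    specs = [("i", config.n_impaired, config.male_prop_impaired,
              config.age_mean_impaired, config.age_sd_impaired,
              config.acuity_mean_impaired, config.acuity_sd_impaired,
              config.acuity_bounds_impaired, config.nystagmus_prevalence),
             ("c", config.n_control, config.male_prop_control,
              config.age_mean_control, config.age_sd_control,
              config.acuity_mean_control, config.acuity_sd_control,
              config.acuity_bounds_control, 0.0)]
    pid = 0
    for (grp, n, male_p, age_m, age_sd, ac_m, ac_sd, ac_b, nyst_p) in specs:
        ages = _truncated_normal(rng, age_m, age_sd, *config.age_bounds, size=n)
        acuity = _truncated_normal(rng, ac_m, ac_sd, *ac_b, size=n)
        genders = np.where(rng.random(n) < male_p, "m", "f")
        nyst = (rng.random(n) < nyst_p).astype(int)
        for j in range(n):
            pid += 1
            rows.append({
                "participant_id": f"P{pid:03d}",
                "group": grp,
                "gender": genders[j],
                "age": round(float(ages[j]), 1),
                "nystagmus": int(nyst[j]),
                "acuity_logmar": round(float(acuity[j]), 2),
                "intercept_shift": rng.normal(0.0, config.participant_sd)
                if config.participant_sd > 0 else 0.0,
            })
    return pd.DataFrame(rows)


def simulate_experiment(config: SimConfig = None,
                        seed: int | None = None) -> SimulatedExperiment:
    """Draw a complete synthetic experiment.

    Returns the trial table in the canonical CSV schema plus the
    ground-truth parameter map used (for recovery checks).  Deterministic
    for a fixed config + seed.
    """
    config = config or SimConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    rt_map = build_rt_parameter_map(config)
    participants = _draw_participants(config, rng)

    acc_map = config.accuracy_map or accuracy_map_default
    acuity_ref = {"i": config.acuity_mean_impaired,
                  "c": config.acuity_mean_control}
    rows = []
    for part in participants.itertuples(index=False):
        practice_idx = rng.integers(0, len(CONDITIONS), size=N_PRACTICE)
        conds = [CONDITIONS[i] for i in practice_idx] + sample_schedule(rng)
        mu_shift = part.intercept_shift
        mu_shift += config.acuity_rt_slope * (part.acuity_logmar
                                              - acuity_ref[part.group])
        for order, (set_size, target) in enumerate(conds, start=1):
            mu, sigma, nu = rt_map[(part.group, _band(set_size), target,
                                    part.gender)]
            rt = float(exgauss_rvs(mu + mu_shift, sigma, nu, None, rng))
            rt = max(rt, 0.05)
            p_correct = acc_map(set_size, target, part.age)
            correct = int(rng.random() < p_correct)
            rows.append({
                "participant_id": part.participant_id,
                "group": part.group,
                "gender": part.gender,
                "age": part.age,
                "nystagmus": part.nystagmus,
                "acuity_logmar": part.acuity_logmar,
                "set_size": set_size,
                "target": target,
                "rt_s": round(rt, 4),
                "correct": correct,
                "order": order,
            })
    trials = pd.DataFrame(rows, columns=CSV_COLUMNS)
    truth = {
        "seed": int(seed),
        "rt_map": {"|".join(k): list(v) for k, v in rt_map.items()},
        "median_map": {"|".join(k): float(v)
                       for k, v in config.median_map.items()},
    }
    return SimulatedExperiment(trials=trials, ground_truth=truth)


def null_config(**overrides) -> SimConfig:
    """A configuration with all effect contrasts zeroed: every cell shares
    one Ex-Gaussian and one accuracy level, so covariates carry no signal."""
    flat = {k: 1.5 for k in default_median_map()}
    cfg = SimConfig(median_map=flat, **overrides)
    return cfg
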