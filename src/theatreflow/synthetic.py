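"""Synthetic theatre-list generator.

Emulates a multi-hospital electronic-patient-record extract of elective
procedures with the statistical structure the downstream analyses assume:
log-normal operating times with a baseline per procedure, a random
intercept shared by every case in the same (procedure, age group, ASA
grade) cell, and additive log-scale effects of absolute list position,
procedure-specific list position, and switching.  For case *i* at absolute
position A, procedure-specific position S, switch indicator W:

    log duration_i = log(baseline(code_i)) + b_cell(i)
                     + beta_abs * (A - 1) + beta_spec * (S - 1)
                     + beta_switch * W + eps_i

with b_cell ~ N(0, tau^2) drawn once per cell and eps ~ N(0, sigma^2).
Log length of stay follows the same form with its own coefficients,
baseline and residual SD.  List composition is first-order Markov in the
procedure sequence: with probability ``p_same`` the next case repeats the
previous procedure, otherwise a fresh code is drawn from the catalogue
weights.  Missing surgeon identifiers, missing start times and duplicated
rows are injected afterwards at configurable rates.

The generator never emits the order codes or the latent effects — the
records module must recompute the coding from the raw rows, exactly as it
would on real data.  :func:`truth_table` exposes the generating parameters
as the recovery oracle for tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import AGE_GROUPS, ASA_GRADES, RECORD_COLUMNS
from .mixed_model import to_percent

#: Default pooled effect sizes (log scale): a 0.39% saving per absolute
#: position, a 0.98% saving per same-procedure repetition, and a 6.48%
#: switching cost.
DEFAULT_BETA_ABS = float(np.log1p(-0.0039))
DEFAULT_BETA_SPEC = float(np.log1p(-0.0098))
DEFAULT_BETA_SWITCH = float(np.log(1.0648))

#: Default length-of-stay coefficients: +0.55% per absolute position,
#: -0.72% per repetition, no switching effect.
DEFAULT_GAMMA_ABS = float(np.log(1.0055))
DEFAULT_GAMMA_SPEC = float(np.log1p(-0.0072))
DEFAULT_GAMMA_SWITCH = 0.0


def default_catalogue(n_codes: int = 35) -> pd.DataFrame:
    """A deterministic 35-procedure catalogue.

    Baseline median durations are log-spaced between 12 and 150 minutes;
    method alternates open / minimally invasive and complexity cycles over
    four ordinal grades, so every stratum is populated.  Sampling weights
    decay with rank (common procedures dominate, as in a real case mix).
    """
    codes = [f"P{i + 1:02d}" for i in range(n_codes)]
    baselines = np.geomspace(12.0, 150.0, n_codes)
    weights = 1.0 / np.sqrt(np.arange(1, n_codes + 1))
    return pd.DataFrame(
        {
            "procedure_code": codes,
            "baseline_min": baselines.round(1),
            "baseline_los_min": (baselines * 12.0).round(0),
            "method": ["open" if i % 2 == 0 else "minimally_invasive" for i in range(n_codes)],
            "complexity": [str(1 + i % 4) for i in range(n_codes)],
            "weight": weights / weights.sum(),
        }
    )


def _truncated_geometric(q: float = 0.78, l_max: int = 12) -> list[float]:
    p = (1 - q) * q ** np.arange(l_max)
    return [float(v) for v in p / p.sum()]


def _plain(obj):
    """Recursively convert numpy scalars for YAML-safe serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic world.

    Defaults describe the study conditions: ~40 000 records once the
    default 9000 lists are drawn (mean list length ≈ 4.4), a case mix over
    35 procedures, a switch fraction near one half, effect sizes equal to
    the pooled estimates the analyses should recover, and noise rates
    matching the observed exclusion-flow proportions.
    """

    n_surgeons: int = 120
    n_hospitals: int = 8
    n_lists: int = 9000
    #: probability of list length 1..len(list_length_law)
    list_length_law: list[float] = field(default_factory=_truncated_geometric)
    #: probability the next case repeats the previous procedure; the
    #: default makes just over half of all cases switches, given the mean
    #: list length and the chance a fresh draw repeats the previous code
    p_same: float = 0.27
    catalogue: pd.DataFrame = field(default_factory=default_catalogue)
    beta_abs: float = DEFAULT_BETA_ABS
    beta_spec: float = DEFAULT_BETA_SPEC
    beta_switch: float = DEFAULT_BETA_SWITCH
    tau: float = 0.25
    sigma: float = 0.35
    age_law: list[float] = field(
        default_factory=lambda: [0.02, 0.04, 0.08, 0.12, 0.18, 0.22, 0.20, 0.14]
    )
    asa_law: list[float] = field(default_factory=lambda: [0.35, 0.45, 0.16, 0.035, 0.005])
    gamma_abs: float = DEFAULT_GAMMA_ABS
    gamma_spec: float = DEFAULT_GAMMA_SPEC
    gamma_switch: float = DEFAULT_GAMMA_SWITCH
    sigma_los: float = 0.55
    p_missing_surgeon: float = 8807 / 478519
    p_missing_start: float = 1422 / 478519
    p_duplicate: float = 32 / 478519
    #: residual law: "normal" or "t" (df 5, scaled to sd sigma) for
    #: misspecification robustness checks
    residual_law: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("list_length_law", "age_law", "asa_law"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.ndim != 1 or (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-8):
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if len(self.age_law) != len(AGE_GROUPS) or len(self.asa_law) != len(ASA_GRADES):
            raise ValueError("age_law / asa_law length must match the category sets")
        if not 0.0 <= self.p_same <= 1.0:
            raise ValueError("p_same must lie in [0, 1]")
        if self.tau < 0 or self.sigma < 0 or self.sigma_los < 0:
            raise ValueError("tau, sigma, sigma_los must be non-negative")
        if (self.catalogue["baseline_min"] <= 0).any():
            raise ValueError("catalogue baselines must be positive")
        if self.residual_law not in ("normal", "t"):
            raise ValueError("residual_law must be 'normal' or 't'")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["catalogue"] = self.catalogue.to_dict(orient="list")
        return _plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "catalogue" in d and not isinstance(d["catalogue"], pd.DataFrame):
            d["catalogue"] = pd.DataFrame(d["catalogue"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def truth_table(cfg: GeneratorConfig) -> dict:
    """Machine-readable dump of the generating parameters (recovery oracle)."""
    return {
        "beta_abs": cfg.beta_abs,
        "beta_spec": cfg.beta_spec,
        "beta_switch": cfg.beta_switch,
        "pct_abs": to_percent(cfg.beta_abs),
        "pct_spec": to_percent(cfg.beta_spec),
        "pct_switch": to_percent(cfg.beta_switch),
        "tau": cfg.tau,
        "sigma": cfg.sigma,
        "gamma_abs": cfg.gamma_abs,
        "gamma_spec": cfg.gamma_spec,
        "gamma_switch": cfg.gamma_switch,
        "pct_los_abs": to_percent(cfg.gamma_abs),
        "pct_los_spec": to_percent(cfg.gamma_spec),
        "pct_los_switch": to_percent(cfg.gamma_switch),
        "sigma_los": cfg.sigma_los,
        "seed": cfg.seed,
    }


def generate_dataset(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate a raw (pre-cleaning) procedure-record table.

    Deterministic: the same config and seed give a bit-identical frame.
    Columns follow the records-module input schema; order codes and latent
    effects are not included.
    """
    rng = np.random.default_rng(cfg.seed)
    cat = cfg.catalogue.reset_index(drop=True)
    n_codes = len(cat)
    code_w = cat["weight"].to_numpy() / cat["weight"].sum()

    # one (surgeon, hospital, date) triple per list, unique so that list
    # reconstruction downstream recovers exactly the generated lists
    dates = pd.date_range("2013-04-01", "2015-05-31", freq="D")
    n_slots = cfg.n_surgeons * len(dates)
    if cfg.n_lists > n_slots:
        raise ValueError("n_lists exceeds available surgeon-date slots")
    slots = rng.choice(n_slots, size=cfg.n_lists, replace=False)
    surgeon_idx, date_idx = np.divmod(slots, len(dates))
    hospital_idx = rng.integers(cfg.n_hospitals, size=cfg.n_lists)

    lengths = rng.choice(
        np.arange(1, len(cfg.list_length_law) + 1), size=cfg.n_lists, p=cfg.list_length_law
    )
    n = int(lengths.sum())
    list_id = np.repeat(np.arange(cfg.n_lists), lengths)

    # Markov procedure sequence within each list
    code = np.empty(n, dtype=int)
    pos_in_list = np.concatenate([np.arange(k) for k in lengths])
    first = pos_in_list == 0
    fresh = rng.choice(n_codes, size=n, p=code_w)
    repeat = rng.random(n) < cfg.p_same
    code[first] = fresh[first]
    for i in np.flatnonzero(~first):
        code[i] = code[i - 1] if repeat[i] else fresh[i]

    abs_no = pos_in_list + 1
    # procedure-specific position and switch, recomputed here only to place
    # the effects; the coded columns are deliberately not emitted
    spec_no = np.empty(n, dtype=int)
    switch = np.zeros(n, dtype=bool)
    seen: dict[int, int] = {}
    for i in range(n):
        if first[i]:
            seen = {}
        seen[code[i]] = seen.get(code[i], 0) + 1
        spec_no[i] = seen[code[i]]
        if not first[i]:
            switch[i] = code[i] != code[i - 1]

    age = rng.choice(len(AGE_GROUPS), size=n, p=cfg.age_law)
    asa = rng.choice(len(ASA_GRADES), size=n, p=cfg.asa_law)

    # cell random intercepts: pre-drawn for every possible cell so draw
    # order (hence determinism) is independent of which cells are realized
    b_dur = rng.normal(0.0, cfg.tau, size=(n_codes, len(AGE_GROUPS), len(ASA_GRADES)))
    b_los = rng.normal(0.0, cfg.tau, size=(n_codes, len(AGE_GROUPS), len(ASA_GRADES)))

    lin = (
        cfg.beta_abs * (abs_no - 1)
        + cfg.beta_spec * (spec_no - 1)
        + cfg.beta_switch * switch
    )
    if cfg.residual_law == "t":
        eps = rng.standard_t(5, size=n) * cfg.sigma / np.sqrt(5 / 3)
        eps_los = rng.standard_t(5, size=n) * cfg.sigma_los / np.sqrt(5 / 3)
    else:
        eps = rng.normal(0.0, cfg.sigma, size=n)
        eps_los = rng.normal(0.0, cfg.sigma_los, size=n)
    log_dur = np.log(cat["baseline_min"].to_numpy()[code]) + b_dur[code, age, asa] + lin + eps
    lin_los = (
        cfg.gamma_abs * (abs_no - 1)
        + cfg.gamma_spec * (spec_no - 1)
        + cfg.gamma_switch * switch
    )
    log_los = (
        np.log(cat["baseline_los_min"].to_numpy()[code]) + b_los[code, age, asa] + lin_los + eps_los
    )

    # fixed 40-minute theatre slots keep within-day ordering simple and total
    minutes = 8 * 60 + pos_in_list * 40
    start_time = np.array([f"{m // 60:02d}:{m % 60:02d}" for m in minutes])

    df = pd.DataFrame(
        {
            "record_id": [f"R{i:07d}" for i in range(n)],
            "surgeon_id": [f"S{surgeon_idx[l]:03d}" for l in list_id],
            "hospital_id": [f"H{hospital_idx[l]:02d}" for l in list_id],
            "list_date": dates[date_idx[list_id]].strftime("%Y-%m-%d"),
            "start_time": start_time,
            "procedure_code": cat["procedure_code"].to_numpy()[code],
            "age_group": np.array(AGE_GROUPS, dtype=object)[age],
            "asa_grade": np.array(ASA_GRADES, dtype=object)[asa],
            "duration_min": np.round(np.exp(log_dur), 2),
            "los_min": np.round(np.exp(log_los), 1),
        }
    )

    # noise injection: blank fields, then re-emit uniformly chosen rows
    blank_s = rng.random(n) < cfg.p_missing_surgeon
    blank_t = rng.random(n) < cfg.p_missing_start
    df.loc[blank_s, "surgeon_id"] = ""
    df.loc[blank_t, "start_time"] = ""
    n_dup = rng.binomial(n, cfg.p_duplicate)
    if n_dup:
        dup_rows = df.iloc[rng.integers(n, size=n_dup)]
        df = pd.concat([df, dup_rows], ignore_index=True)

    df["duration_min"] = df["duration_min"].map(lambda v: f"{v:.2f}")
    df["los_min"] = df["los_min"].map(lambda v: f"{v:.1f}")
    return df.loc[:, RECORD_COLUMNS]


def catalogue_mapping(cat: pd.DataFrame) -> dict:
    """The catalogue's method/complexity columns as a classify() mapping."""
    return {
        row.procedure_code: {"method": row.method, "complexity": row.complexity}
        for row in cat.itertuples()
    }
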