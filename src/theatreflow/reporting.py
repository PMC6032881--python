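"""End-to-end pipeline assembly and tabular reports.

The pipeline runs clean → list building → order coding → classification →
mixed-model fits (duration and length of stay) → matched analyses (pooled,
per procedure, stratified by method and complexity) and writes every
product as CSV/JSON, plus a manifest sufficient to replay the run.
Forest-style tables mirror the usual effect-size figure: an Overall row
first, then one row per procedure or stratum, each with a percent change
and its 95% CI (negative values are reductions in operating time).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import records as rec
from . import synthetic
from .matched import MatchResult, match_pairs, paired_effect, per_procedure_matched, stratified_matched
from .mixed_model import EffectEstimate, ModelFit, effects_table, fit_lmm, per_procedure_fits

logger = logging.getLogger("theatreflow")


@dataclass(frozen=True)
class ForestRow:
    """One line of a forest table: a label, a percent effect, its CI, n."""

    label: str
    pct: float
    pct_low: float
    pct_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.pct_low <= self.pct <= self.pct_high) and np.isfinite(self.pct):
            raise ValueError("forest row CI must bracket the estimate")


def forest_table(
    overall: EffectEstimate | ModelFit,
    per_label: dict[str, EffectEstimate | ModelFit] | None = None,
    effect: str = "switch",
) -> list[ForestRow]:
    """Assemble forest rows: Overall first, then labels in sorted order.

    ``effect`` selects the coefficient when ModelFit objects are passed;
    plain EffectEstimate values (matched results) are used directly.
    """

    def to_row(label: str, est: EffectEstimate | ModelFit) -> ForestRow:
        e = est.effect(effect) if isinstance(est, ModelFit) else est
        return ForestRow(label, e.pct, e.pct_low, e.pct_high, e.n)

    rows = [to_row("Overall", overall)]
    for label in sorted(per_label or {}):
        rows.append(to_row(label, per_label[label]))
    return rows


def forest_frame(rows: list[ForestRow]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in rows])


def position_profile(
    coded: pd.DataFrame, code: str, max_position: int = 10, min_n: int = 5
) -> pd.DataFrame:
    """Mean duration (with normal 95% CI) by procedure-specific position.

    Positions with fewer than ``min_n`` cases are suppressed; an absent
    code yields an empty table.  Durations are arithmetic means in
    minutes, the natural display scale for a position profile.
    """
    sub = coded.loc[
        (coded["procedure_code"] == code)
        & (coded["procedure_specific_list_no"] <= max_position)
    ]
    rows = []
    z = float(stats.norm.ppf(0.975))
    for pos, grp in sub.groupby("procedure_specific_list_no", sort=True):
        n = len(grp)
        if n < min_n:
            continue
        d = grp["duration_min"].to_numpy(float)
        m = d.mean()
        half = z * d.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        rows.append(
            {"position": int(pos), "mean_duration": m, "ci_low": m - half, "ci_high": m + half, "n": n}
        )
    return pd.DataFrame(rows, columns=["position", "mean_duration", "ci_low", "ci_high", "n"])


@dataclass
class RunManifest:
    """Everything needed to replay a pipeline run bit-identically."""

    config_hash: str
    seed: int
    software_version: str
    input_path: str
    exclusion_summary: dict
    stage_counts: dict[str, int] = field(default_factory=dict)
    artifacts: list[str] = field(default_factory=list)
    skipped: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


DEFAULT_PIPELINE = {
    "input": None,  # raw CSV path; or use "simulate"
    "simulate": None,  # GeneratorConfig dict; generates the input
    "mapping": "catalogue",  # mapping file path, or "catalogue" when simulating
    "include_hospital": True,
    "k": 1,
    "min_cases": 200,
    "seed": 0,
    "fit_duration": True,
    "fit_los": True,
    "match": True,
    "per_procedure": True,
    "stratified": True,
}


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Run the full analysis chain and write all artifacts under out_dir.

    ``config`` follows :data:`DEFAULT_PIPELINE`; provide either ``input``
    (a raw records CSV) or ``simulate`` (generator parameters; may be an
    empty dict for the defaults).  Any stage failure aborts with the stage
    name in the exception.
    """
    cfg = {**DEFAULT_PIPELINE, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: list[str] = []
    skipped: dict[str, list[str]] = {}
    counts: dict[str, int] = {}

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        artifacts.append(name)

    # --- input -----------------------------------------------------------
    stage = "input"
    try:
        if cfg["simulate"] is not None:
            gen_cfg = synthetic.GeneratorConfig.from_dict({"seed": seed, **cfg["simulate"]})
            raw = synthetic.generate_dataset(gen_cfg)
            input_path = str(out / "simulated.csv")
            raw.to_csv(input_path, index=False)
            artifacts.append("simulated.csv")
            Path(out / "truth.json").write_text(
                json.dumps(synthetic.truth_table(gen_cfg), indent=2) + "\n"
            )
            artifacts.append("truth.json")
            mapping = synthetic.catalogue_mapping(gen_cfg.catalogue)
        elif cfg["input"]:
            input_path = str(cfg["input"])
            raw = rec.load_records(input_path)
            mapping = rec.load_mapping(cfg["mapping"]) if cfg["mapping"] != "catalogue" else {}
        else:
            raise ValueError("config must provide 'input' or 'simulate'")

        stage = "clean"
        clean, summary = rec.clean_records(raw)
        summary.to_json(out / "exclusions.json")
        artifacts.append("exclusions.json")
        counts["raw"] = summary.n_input
        counts["clean"] = summary.n_retained

        stage = "code"
        coded = rec.code_records(clean, include_hospital=bool(cfg["include_hospital"]))
        coded = rec.classify(coded, mapping)
        save_df(coded, "coded.csv")
        counts["coded"] = len(coded)

        stage = "fit"
        if cfg["fit_duration"]:
            fit = fit_lmm(coded, outcome="duration")
            effects_table(fit).to_csv(out / "lmm_duration.csv", index=False)
            artifacts.append("lmm_duration.csv")
            if cfg["per_procedure"]:
                fits, skip = per_procedure_fits(coded, "duration", min_cases=int(cfg["min_cases"]))
                effects_table(fits).to_csv(out / "lmm_duration_by_procedure.csv", index=False)
                artifacts.append("lmm_duration_by_procedure.csv")
                skipped["lmm_per_procedure"] = skip
                for eff in ("absolute_order", "specific_order", "switch"):
                    save_df(
                        forest_frame(forest_table(fit, fits, effect=eff)),
                        f"forest_lmm_{eff}.csv",
                    )
        if cfg["fit_los"]:
            fit_los = fit_lmm(coded, outcome="length_of_stay")
            effects_table(fit_los).to_csv(out / "lmm_los.csv", index=False)
            artifacts.append("lmm_los.csv")

        stage = "match"
        if cfg["match"]:
            k = int(cfg["k"])
            res = match_pairs(coded, k=k, seed=seed)
            save_df(res.pairs, "pairs.csv")
            counts["pairs"] = res.n_matched
            counts["pair_candidates_first"] = res.n_candidates_first
            counts["pair_candidates_second"] = res.n_candidates_second
            pooled = paired_effect(res)
            per_code: dict[str, EffectEstimate] = {}
            if cfg["per_procedure"]:
                per_code, skip = per_procedure_matched(coded, k=k, seed=seed)
                skipped["matched_per_procedure"] = skip
            save_df(forest_frame(forest_table(pooled, per_code)), "forest_matched.csv")
            if cfg["stratified"]:
                for strat in ("method", "complexity"):
                    eff, skip, n_uncl = stratified_matched(coded, strat, k=k, seed=seed)
                    skipped[f"matched_{strat}"] = skip
                    counts[f"unclassified_{strat}"] = n_uncl
                    save_df(forest_frame(forest_table(pooled, eff)), f"forest_matched_{strat}.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config_hash=_hash_config(cfg),
        seed=seed,
        software_version=_version(),
        input_path=input_path,
        exclusion_summary=summary.to_dict(),
        stage_counts=counts,
        artifacts=artifacts,
        skipped=skipped,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
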