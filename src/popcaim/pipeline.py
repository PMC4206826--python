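"""Configuration-driven orchestration.

``run_pipeline`` composes the full analysis on generated data: synthetic
experiment -> dF/F (V2L dialect, +/-2.5 s sliding median) -> per-cell
metrics and per-repetition response vectors -> per-animal pattern similarity
and occurrence reliability -> group-level mixed ANOVA and Ryan post hoc ->
CSV tables and a reproducibility manifest.  Everything is deterministic given
the seed.

The first 10 s of each recording are excluded from display windows by
default (mechanical onset artifacts in the raw movies); the stimulus
schedule places all analysis windows after that.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ExperimentDesign
from .dff import (
    V2L_HALF_WINDOW_S, VTA_HALF_WINDOW_S, compute_dff, detect_occurrence,
    response_vector, summed_response,
)
from .population import cronbach_alpha, correlate_response_gain, ks_two_sample, \
    pattern_similarity, responder_distribution
from .stats import mixed_anova, oneway_anova, rm_oneway_anova, ryan_posthoc
from .synthetic import SimConfig, simulate_experiment

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "summarize_effects"]

TABLE_NAMES = (
    "pop_dff", "dff_change", "similarity", "per_cell_metrics",
    "anova_dff", "anova_similarity", "posthoc_dff_change",
    "posthoc_similarity", "responders", "correlation", "ks", "popavg_trace",
)


@dataclass
class PipelineConfig:
    """Everything one run needs: generator settings plus analysis knobs."""

    sim: SimConfig = field(default_factory=SimConfig)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    dff_half_window_s: float = V2L_HALF_WINDOW_S
    vta_dff_half_window_s: float = VTA_HALF_WINDOW_S
    response_summary: str = "peak"
    response_window_s: float = 5.0
    occurrence_k_sd: float = 3.0
    occurrence_binary_alpha: bool = True
    responder_threshold: float = 0.2
    vta_sum_window_s: tuple[float, float] = (30.0, 50.0)
    exclude_first_s: float = 10.0
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        cfg = dict(cfg)
        known = {f for f in cls.__dataclass_fields__}
        bad = [k for k in cfg if k not in known]
        if bad:
            raise ValueError(f"unknown config key(s): {bad}")
        if "sim" in cfg and isinstance(cfg["sim"], dict):
            sim = dict(cfg["sim"])
            sim_known = set(SimConfig.__dataclass_fields__)
            sim_bad = [k for k in sim if k not in sim_known]
            if sim_bad:
                raise ValueError(f"unknown config key(s) under sim: {sim_bad}")
            for key in ("n_cells", "stim_times_s"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            if "paradigm_effects" in sim and sim["paradigm_effects"] is not None:
                sim["paradigm_effects"] = {
                    par: {tp: tuple(v) for tp, v in per.items()}
                    for par, per in sim["paradigm_effects"].items()
                }
            cfg["sim"] = SimConfig(**sim)
        if "design" in cfg and isinstance(cfg["design"], dict):
            d = dict(cfg["design"])
            for key in ("paradigms", "time_points"):
                if key in d and isinstance(d[key], list):
                    d[key] = tuple(d[key])
            cfg["design"] = ExperimentDesign(**d)
        if "vta_sum_window_s" in cfg and isinstance(cfg["vta_sum_window_s"], list):
            cfg["vta_sum_window_s"] = tuple(cfg["vta_sum_window_s"])
        return cls(**cfg)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: list


def _config_hash(config: PipelineConfig) -> str:
    canon = yaml.safe_dump(_jsonable(config.to_dict()), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(
    config: PipelineConfig | dict | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
):
    """Run the full analysis; returns ``(RunManifest, tables)``.

    ``tables`` is a dict of pandas DataFrames (see :data:`TABLE_NAMES`).
    When ``outdir`` is given every table is written as CSV alongside
    ``manifest.json``.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    if seed is not None:
        config.seed = int(seed)

    design, sim = config.design, config.sim
    exp = simulate_experiment(design, sim, seed=config.seed)
    fps = sim.fps
    reps = design.n_repetitions

    pop_rows, sim_rows, cell_rows = [], [], []
    vectors = {}   # (paradigm, animal, tp) -> cells x reps response matrix
    for (par, ai, tp), tm in exp.traces.items():
        dff = compute_dff(tm.data, fps, config.dff_half_window_s)
        vecs = np.column_stack([
            response_vector(dff, fps, ev.time_s,
                            summary=config.response_summary,
                            window_s=config.response_window_s)
            for ev in tm.events
        ])
        vectors[(par, ai, tp)] = vecs
        pop_dff = float(vecs.mean(axis=0).mean())  # cells averaged, then repetitions
        pop_rows.append(dict(paradigm=par, animal=ai, time_point=tp, pop_dff=pop_dff))

        sim_res = pattern_similarity(*(vecs[:, r] for r in range(reps)))
        occ = np.array([
            [detect_occurrence(dff[c], fps, ev.time_s,
                               response_window_s=config.response_window_s,
                               k_sd=config.occurrence_k_sd)
             for c in range(dff.shape[0])]
            for ev in tm.events
        ], dtype=float)
        scores = occ if config.occurrence_binary_alpha else vecs.T
        try:
            rel = cronbach_alpha(scores)
            alpha_val, ci = rel.alpha, rel.ci95
        except ValueError:
            alpha_val, ci = np.nan, (np.nan, np.nan)
        sim_rows.append(dict(
            animal=ai, paradigm=par, time_point=tp,
            pair_12=sim_res.pair_12, pair_23=sim_res.pair_23,
            pair_13=sim_res.pair_13, mean_cosine=sim_res.mean_cosine,
            alpha=alpha_val, ci_low=ci[0], ci_high=ci[1],
        ))

        sums = np.column_stack([
            np.array([
                summed_response(dff[c], fps,
                                (ev.time_s, ev.time_s + config.response_window_s)).summed_dff
                for c in range(dff.shape[0])
            ])
            for ev in tm.events
        ])
        for c in range(dff.shape[0]):
            cell_rows.append(dict(
                paradigm=par, animal=ai, time_point=tp, cell_id=int(tm.cell_ids[c]),
                peak_dff=float(vecs[c].mean()), summed_dff=float(sums[c].mean()),
                occurrence_count=int(occ[:, c].sum()),
            ))

    pop_df = pd.DataFrame(pop_rows)
    sim_df = pd.DataFrame(sim_rows)
    cell_df = pd.DataFrame(cell_rows)

    # dF/F(2hr - before) per animal
    tp_first, tp_last = design.time_points[0], design.time_points[-1]
    wide = pop_df.pivot_table(index=["paradigm", "animal"], columns="time_point",
                              values="pop_dff")
    delta = (wide[tp_last] - wide[tp_first]).rename("dff_2hr_minus_before").reset_index()

    # group-level inference (animal indices restart per group; build unique ids)
    for df_ in (pop_df, sim_df):
        df_["subject"] = df_["paradigm"].astype(str) + "_" + df_["animal"].astype(str)
    anova_dff = mixed_anova(pop_df, dv="pop_dff", subject="subject")
    anova_sim = mixed_anova(sim_df, dv="mean_cosine", subject="subject")
    pop_df = pop_df.drop(columns="subject")
    sim_df = sim_df.drop(columns="subject")

    one = oneway_anova([
        delta.loc[delta["paradigm"] == par, "dff_2hr_minus_before"].to_numpy()
        for par in design.paradigms
    ])
    grp = delta.groupby("paradigm")["dff_2hr_minus_before"]
    grp_means = grp.mean().loc[list(design.paradigms)]
    resid = delta.set_index("paradigm")["dff_2hr_minus_before"] - grp.transform("mean").values
    ms_within = float((resid ** 2).sum() / one["df"][1])
    ph_delta = ryan_posthoc(
        grp_means.to_numpy(), sim.n_animals_per_paradigm, ms_within, one["df"][1],
        alpha=config.alpha, labels=list(grp_means.index),
    ).table
    ph_delta.insert(0, "oneway_F", one["F"])
    ph_delta.insert(1, "oneway_p", one["p"])

    # per-paradigm Ryan test on similarity across time points
    ph_sim_rows = []
    for par in design.paradigms:
        y = (sim_df[sim_df["paradigm"] == par]
             .pivot_table(index="animal", columns="time_point", values="mean_cosine")
             .loc[:, list(design.time_points)].to_numpy())
        rm = rm_oneway_anova(y)
        ph = ryan_posthoc(
            y.mean(axis=0), y.shape[0], rm["ms_error"], rm["df_error"],
            alpha=config.alpha, labels=list(design.time_points),
        ).table
        ph.insert(0, "paradigm", par)
        ph.insert(1, "rm_F", rm["F"])
        ph.insert(2, "rm_p", rm["p"])
        ph_sim_rows.append(ph)
    ph_sim = pd.concat(ph_sim_rows, ignore_index=True)

    # responder distributions (cells pooled across animals within paradigm/tp)
    resp_rows = []
    for (par, tp), sub in cell_df.groupby(["paradigm", "time_point"], sort=False):
        dist = responder_distribution(sub["peak_dff"].to_numpy(),
                                      threshold=config.responder_threshold)
        resp_rows.append(dict(paradigm=par, time_point=tp,
                              fraction_above=dist.fraction_above, n=dist.n))
    resp_df = pd.DataFrame(resp_rows)

    # per-animal correlation: VTA-evoked summed dF/F vs per-cell response change
    corr_rows = []
    for (par, ai), tm in exp.vta_traces.items():
        dff = compute_dff(tm.data, fps, config.vta_dff_half_window_s)
        vta_sum = np.array([
            summed_response(dff[c], fps, config.vta_sum_window_s).summed_dff
            for c in range(dff.shape[0])
        ])
        cell_delta = (vectors[(par, ai, tp_last)].mean(axis=1)
                      - vectors[(par, ai, tp_first)].mean(axis=1))
        try:
            r, p = correlate_response_gain(vta_sum, cell_delta)
        except ValueError:
            r, p = np.nan, np.nan
        corr_rows.append(dict(paradigm=par, animal=ai, r=r, p=p,
                              n_cells=len(vta_sum)))
    corr_df = pd.DataFrame(corr_rows)

    # distribution comparisons across selected conditions (pooled cells)
    ks_rows = []
    if "T1" in design.paradigms and "1hr" in design.time_points:
        pool = lambda par, tp: cell_df.loc[
            (cell_df["paradigm"] == par) & (cell_df["time_point"] == tp), "peak_dff"
        ].to_numpy()
        ref = pool("T1", "1hr")
        for other_par in ("VTA_only", "T2"):
            if other_par in design.paradigms:
                d, p = ks_two_sample(ref, pool(other_par, tp_last))
                ks_rows.append(dict(sample_x="T1@1hr", sample_y=f"{other_par}@{tp_last}",
                                    D=d, p=p))
    ks_df = pd.DataFrame(ks_rows, columns=["sample_x", "sample_y", "D", "p"])

    # representative population-average trace (first paradigm/animal, baseline tp)
    par0 = design.paradigms[0]
    tm0 = exp.traces[(par0, 0, tp_first)]
    dff0 = compute_dff(tm0.data, fps, config.dff_half_window_s)
    t0 = tm0.time
    show = t0 >= config.exclude_first_s
    popavg = pd.DataFrame({
        "time_s": t0[show],
        "mean_dff": dff0[:, show].mean(axis=0),
        "sem_dff": dff0[:, show].std(axis=0, ddof=1) / np.sqrt(dff0.shape[0]),
    })
    popavg.attrs["events"] = [ev.time_s for ev in tm0.events]

    tables = {
        "pop_dff": pop_df, "dff_change": delta, "similarity": sim_df,
        "per_cell_metrics": cell_df, "anova_dff": anova_dff,
        "anova_similarity": anova_sim, "posthoc_dff_change": ph_delta,
        "posthoc_similarity": ph_sim, "responders": resp_df,
        "correlation": corr_df, "ks": ks_df, "popavg_trace": popavg,
    }

    outputs = []
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            outputs.append(path.name)
        manifest = RunManifest(
            config_hash=_config_hash(config), seed=config.seed,
            version=__version__, outputs=sorted(outputs),
        )
        (outdir / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    else:
        manifest = RunManifest(
            config_hash=_config_hash(config), seed=config.seed,
            version=__version__, outputs=[],
        )
    return manifest, tables


def summarize_effects(tables: dict, alpha: float = 0.05) -> dict:
    """Condensed answers to the study's headline questions.

    Returns which paradigm shows the largest dF/F(2hr - before), whether the
    paradigm x time interaction is significant for dF/F and for similarity,
    and — per paradigm — whether the (first, last) time-point pattern
    similarity comparison is significant with the last time point higher.
    """
    delta = tables["dff_change"]
    grp = delta.groupby("paradigm")["dff_2hr_minus_before"].mean()
    largest = str(grp.idxmax())

    def _interaction_p(tbl):
        return float(tbl.loc[tbl["effect"] == "interaction", "p"].iloc[0])

    ph = tables["posthoc_similarity"]
    tps = tables["similarity"]["time_point"].unique()
    sim_sig = {}
    for par, sub in ph.groupby("paradigm"):
        first_last = sub[
            ((sub["level_i"] == "before") & (sub["level_j"] == "2hr"))
            | ((sub["level_i"] == "2hr") & (sub["level_j"] == "before"))
        ]
        if len(first_last):
            row = first_last.iloc[0]
            increased = (row["mean_diff"] > 0) == (row["level_i"] == "2hr")
            sim_sig[par] = bool(row["significant"] and increased)
        else:
            sim_sig[par] = False
    return {
        "largest_delta_paradigm": largest,
        "interaction_p_dff": _interaction_p(tables["anova_dff"]),
        "interaction_p_similarity": _interaction_p(tables["anova_similarity"]),
        "similarity_increase_significant": sim_sig,
        "n_time_points": int(len(tps)),
    }
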