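"""Group-comparison statistics and the end-to-end synthetic pipeline runner.

The testing scheme mirrors standard practice for this kind of behavioral
data: a variance-homogeneity gate (Brown–Forsythe by default, Bartlett
switchable) decides between one-way ANOVA with Tukey's post hoc and
Kruskal–Wallis with Dunn's post hoc (Holm-adjusted).  Note the gate tests
variance homogeneity, not normality, even though such gates are often
loosely called normality checks; an optional Shapiro–Wilk add-on is
available.  Every decision the gate makes is reported in the output trail.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from . import activity as act
from . import geotaxis as geo
from . import interaction as inter
from . import networks as nets
from . import redox as rdx
from . import synthetic as syn

__all__ = ["StatsPolicy", "GroupComparison", "choose_and_test", "dunn_test", "run_pipeline"]


@dataclass(frozen=True)
class StatsPolicy:
    """How the parametric / rank-based branch is chosen."""

    alpha: float = 0.05
    gate: str = "brown_forsythe"  # or "bartlett"
    force_branch: Optional[str] = None  # None | "anova" | "kruskal"
    posthoc_adjust: str = "holm"
    posthoc_always: bool = False
    shapiro_addon: bool = False

    def __post_init__(self):
        if self.gate not in ("brown_forsythe", "bartlett"):
            raise ValueError("gate must be 'brown_forsythe' or 'bartlett'")
        if self.force_branch not in (None, "anova", "kruskal"):
            raise ValueError("force_branch must be None, 'anova' or 'kruskal'")


@dataclass
class GroupComparison:
    """Full decision trail for one measure's group comparison."""

    measure: str
    groups: dict
    gate_test: str
    gate_p: float
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    posthoc_test: str
    posthoc: Optional[pd.DataFrame]
    alpha: float
    degenerate: bool = False
    shapiro_p: dict = field(default_factory=dict)


def dunn_test(values_by_group: dict, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal–Wallis.

    z statistics on mean ranks with the standard tie correction; two-sided
    p-values adjusted with the chosen method (statsmodels).
    """
    names = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, pos = {}, {}, 0
    for g, s in zip(names, samples):
        mean_ranks[g] = float(np.mean(ranks[pos : pos + len(s)]))
        sizes[g] = len(s)
        pos += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"group1": a, "group2": b, "statistic": z, "p_raw": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"].fillna(1.0), method=adjust)[1]
    return out


def _tukey_frame(values_by_group: dict) -> pd.DataFrame:
    vals = np.concatenate([np.asarray(v, dtype=float) for v in values_by_group.values()])
    labs = np.concatenate([[g] * len(v) for g, v in values_by_group.items()])
    res = pairwise_tukeyhsd(vals, labs)
    df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return pd.DataFrame(
        {"group1": df["group1"], "group2": df["group2"],
         "statistic": df["meandiff"].astype(float), "p_raw": df["p-adj"].astype(float),
         "p_adj": df["p-adj"].astype(float)}
    )


def choose_and_test(values_by_group: dict, policy: StatsPolicy = StatsPolicy(),
                    measure: str = "") -> GroupComparison:
    """Gate, omnibus test, and (when warranted) post hoc for one measure.

    ``values_by_group`` maps group label -> per-replicate values (≥ 2 groups,
    ≥ 3 values each).  The post hoc is reported when the omnibus p < alpha
    (always, if the policy says so).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 3 for v in groups.values()):
        raise ValueError("need at least 3 values per group")
    samples = list(groups.values())

    if all(np.ptp(v) == 0 for v in samples):
        return GroupComparison(measure, groups, "none", np.nan, "none", np.nan,
                               np.nan, "none", None, policy.alpha, degenerate=True)

    if policy.gate == "brown_forsythe":
        gate_name, (gate_stat, gate_p) = "brown_forsythe", stats.levene(*samples, center="median")
    else:
        gate_name, (gate_stat, gate_p) = "bartlett", stats.bartlett(*samples)

    shapiro_p = {}
    if policy.shapiro_addon:
        for g, v in groups.items():
            shapiro_p[g] = float(stats.shapiro(v).pvalue) if np.ptp(v) > 0 else np.nan

    branch = policy.force_branch
    if branch is None:
        branch = "anova" if gate_p >= policy.alpha else "kruskal"
        if shapiro_p and any(p < policy.alpha for p in shapiro_p.values() if np.isfinite(p)):
            branch = "kruskal"

    if branch == "anova":
        stat, p = stats.f_oneway(*samples)
        omnibus, posthoc_name = "one_way_anova", "tukey_hsd"
        posthoc_fn = lambda: _tukey_frame(groups)
    else:
        stat, p = stats.kruskal(*samples)
        omnibus, posthoc_name = "kruskal_wallis", "dunn"
        posthoc_fn = lambda: dunn_test(groups, adjust=policy.posthoc_adjust)

    posthoc = posthoc_fn() if (p < policy.alpha or policy.posthoc_always) else None
    return GroupComparison(measure, groups, gate_name, float(gate_p), omnibus,
                           float(stat), float(p), posthoc_name, posthoc,
                           policy.alpha, shapiro_p=shapiro_p)


# ---------------------------------------------------------------------------
# end-to-end synthetic pipeline


def _comparison_rows(comp: GroupComparison) -> list[dict]:
    rows = [{
        "measure": comp.measure, "kind": "omnibus", "group1": "", "group2": "",
        "test": comp.omnibus_test, "statistic": comp.omnibus_stat, "p": comp.omnibus_p,
        "gate_test": comp.gate_test, "gate_p": comp.gate_p,
        "significant": bool(comp.omnibus_p < comp.alpha) if np.isfinite(comp.omnibus_p) else False,
        "degenerate": comp.degenerate,
    }]
    if comp.posthoc is not None:
        for _, r in comp.posthoc.iterrows():
            rows.append({
                "measure": comp.measure, "kind": "posthoc",
                "group1": r["group1"], "group2": r["group2"], "test": comp.posthoc_test,
                "statistic": r["statistic"], "p": r["p_adj"],
                "gate_test": comp.gate_test, "gate_p": comp.gate_p,
                "significant": bool(r["p_adj"] < comp.alpha), "degenerate": False,
            })
    return rows


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def _stage_sin(cfg, seed, outdir, echo, comparisons):
    criteria = inter.InteractionCriteria(**cfg.get("criteria", {}))
    arena = syn.ArenaSpec(
        frame_rate_hz=cfg.get("frame_rate_hz", 30.0),
        duration_s=cfg.get("duration_s", 60.0),
    )
    n_flies = cfg.get("n_flies", 12)
    null_spec = nets.NullModelSpec(
        n_random_networks=cfg.get("n_random_networks", 200), group_size=n_flies
    )
    echo["sin"] = {
        "max_distance_mm": criteria.max_distance_mm,
        "max_facing_angle_deg": criteria.max_facing_angle_deg,
        "min_duration_s": criteria.min_duration_s,
        "frame_rate_hz": arena.frame_rate_hz,
        "duration_s": arena.duration_s,
        "n_flies": n_flies,
        "n_random_networks": null_spec.n_random_networks,
    }
    ss = np.random.SeedSequence(seed)
    tables, z_by_measure = [], {}
    for gi, (genotype, gcfg) in enumerate(sorted(cfg["genotypes"].items())):
        profile = syn.SocialProfile(
            attraction_strength=gcfg.get("attraction_strength", 0.0),
            step_speed_mm_s=gcfg.get("step_speed_mm_s", 5.0),
        )
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(gi,))
        seeds = child.generate_state(gcfg.get("n_recordings", 4) + 1)
        recordings, graphs = [], []
        for ri in range(gcfg.get("n_recordings", 4)):
            tracks = syn.simulate_trajectories(arena, n_flies, profile, int(seeds[ri] % 2**31))
            recordings.append(tracks)
            ev = inter.detect_events(tracks, criteria, arena.frame_rate_hz)
            graphs.append(inter.build_network(ev, n_flies, recording_id=f"{genotype}_{ri}",
                                              genotype=genotype))
        nulls = nets.build_random_networks(recordings, null_spec, criteria,
                                           arena.frame_rate_hz,
                                           rng=int(seeds[-1] % 2**31))
        tab = nets.zscore_table(graphs, nulls)
        tables.append(tab)
        for (metric, mode), sub in tab.groupby(["metric", "weight_mode"]):
            z_by_measure.setdefault(f"sin_z::{metric}::{mode}", {})[genotype] = \
                sub["z"].to_numpy()
    _write(pd.concat(tables, ignore_index=True), outdir / "sin_zscores.csv")
    for measure, by_group in sorted(z_by_measure.items()):
        comparisons.append((measure, by_group))


def _stage_activity(cfg, seed, outdir, echo, comparisons):
    n_days = cfg.get("n_days", 5)
    n_flies = cfg.get("n_flies", 8)
    echo["activity"] = {"n_days": n_days, "n_flies": n_flies,
                        "sleep_rule": "zero run strictly > 5 min",
                        "lights_on_h": 8.0, "lights_off_h": 20.0}
    ss = np.random.SeedSequence(seed)
    rows, sleep_rows, period_rows = [], [], []
    by_measure: dict = {}
    for gi, (genotype, gcfg) in enumerate(sorted(cfg["genotypes"].items())):
        prof = syn.ActivityProfile(**{k: v for k, v in gcfg.items() if k != "estimate_period"})
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(1000 + gi,))
        seeds = child.generate_state(2 * n_flies)
        for fi in range(n_flies):
            s = syn.simulate_activity(prof, n_days, seed=int(seeds[fi] % 2**31), fly_id=fi)
            light = act.phase_summary(s, "light")
            dark = act.phase_summary(s, "dark")
            rows.append({"genotype": genotype, "fly": fi,
                         "light_mean_per_min": light, "dark_mean_per_min": dark})
            by_measure.setdefault("activity::light_mean", {}).setdefault(genotype, []).append(light)
            by_measure.setdefault("activity::dark_mean", {}).setdefault(genotype, []).append(dark)
            sp = act.sleep_by_phase(s)
            day_sleep = sp.loc[sp["phase"] == "light", "sleep_min"].mean()
            night_sleep = sp.loc[sp["phase"] == "dark", "sleep_min"].mean()
            sleep_rows.append({"genotype": genotype, "fly": fi,
                               "day_sleep_min": day_sleep, "night_sleep_min": night_sleep})
            by_measure.setdefault("sleep::day_min", {}).setdefault(genotype, []).append(day_sleep)
        if gcfg.get("estimate_period", cfg.get("estimate_period", False)):
            for fi in range(n_flies):
                s = syn.simulate_activity(prof, max(n_days, 5),
                                          seed=int(seeds[n_flies + fi] % 2**31),
                                          constant_darkness=True, fly_id=fi)
                est = act.estimate_period(s)
                period_rows.append({"genotype": genotype, "fly": fi,
                                    "period_h": est.period_h,
                                    "significant": est.significant})
                by_measure.setdefault("circadian::period_h", {}).setdefault(genotype, []).append(est.period_h)
    _write(pd.DataFrame(rows), outdir / "activity_summary.csv")
    _write(pd.DataFrame(sleep_rows), outdir / "sleep_summary.csv")
    if period_rows:
        _write(pd.DataFrame(period_rows), outdir / "circadian_period.csv")
    for measure, by_group in sorted(by_measure.items()):
        comparisons.append((measure, by_group))


def _stage_geotaxis(cfg, seed, outdir, echo, comparisons):
    echo["geotaxis"] = {"n_groups": cfg.get("n_groups", 5),
                        "flies_per_group": cfg.get("flies_per_group", 10),
                        "trials_per_group": cfg.get("trials_per_group", 5),
                        "replication_unit": "group"}
    ss = np.random.SeedSequence(seed)
    tabs = []
    for gi, (genotype, gcfg) in enumerate(sorted(cfg["genotypes"].items())):
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(2000 + gi,))
        tabs.append(syn.simulate_geotaxis(
            gcfg["p_climb"], cfg.get("n_groups", 5), cfg.get("flies_per_group", 10),
            cfg.get("trials_per_group", 5), seed=int(child.generate_state(1)[0] % 2**31),
            genotype=genotype))
    trials = pd.concat(tabs, ignore_index=True)
    group_scores, summary = geo.aggregate(trials)
    _write(trials, outdir / "geotaxis_trials.csv")
    _write(group_scores, outdir / "geotaxis_groups.csv")
    _write(summary, outdir / "geotaxis_summary.csv")
    by_group = {g: sub["score_pct"].to_numpy()
                for g, sub in group_scores.groupby("genotype")}
    comparisons.append(("geotaxis::score_pct", by_group))


def _stage_redox(cfg, seed, outdir, echo, comparisons):
    n_samples = cfg.get("n_samples", 9)
    noise = cfg.get("noise_sd", 0.002)
    echo["redox"] = {"n_samples": n_samples, "noise_sd": noise,
                     "gssg_formula": "(total - free) / 2"}
    ss = np.random.SeedSequence(seed)
    results, by_measure = [], {}
    for gi, (genotype, gcfg) in enumerate(sorted(cfg["genotypes"].items())):
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(3000 + gi,))
        seeds = child.generate_state(n_samples)
        parts = [syn.simulate_assay_readings(gcfg["gsh_uM"], gcfg["gssg_uM"],
                                             noise_sd=noise, seed=int(seeds[k] % 2**31),
                                             sample_id=f"{genotype}_{k}")
                 for k in range(n_samples)]
        table = rdx.analyze_assay_table(pd.concat(parts, ignore_index=True))
        table.insert(0, "genotype", genotype)
        results.append(table)
        by_measure.setdefault("redox::free_gsh_uM", {})[genotype] = table["free_gsh"].to_numpy()
        by_measure.setdefault("redox::gssg_uM", {})[genotype] = table["gssg"].to_numpy()
    _write(pd.concat(results, ignore_index=True), outdir / "redox_results.csv")
    for measure, by_group in sorted(by_measure.items()):
        comparisons.append((measure, by_group))


_STAGES = {"sin": _stage_sin, "activity": _stage_activity,
           "geotaxis": _stage_geotaxis, "redox": _stage_redox}


def run_pipeline(config, out_dir, seed: Optional[int] = None,
                 keep_going: bool = True) -> dict:
    """Run the configured stages end to end on synthetic inputs.

    ``config`` is a dict or a YAML path with a ``stages`` mapping (any subset
    of ``sin``, ``activity``, ``geotaxis``, ``redox``; each stage names its
    genotypes and parameters) and an optional ``stats`` policy.  Writes tidy
    CSVs, ``group_comparisons.csv``, a methods echo (every threshold actually
    used) and the seeds under ``out_dir``.  Deterministic given the seed:
    repeated runs are byte-identical.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    policy = StatsPolicy(**config.get("stats", {}))
    echo: dict = {"seed": seed, "stats_policy": {"alpha": policy.alpha, "gate": policy.gate,
                                                 "posthoc_adjust": policy.posthoc_adjust}}
    comparisons: list = []
    failures: dict = {}
    stage_seeds = {name: seed + 17 * (k + 1)
                   for k, name in enumerate(sorted(config.get("stages", {})))}
    for name in sorted(config.get("stages", {})):
        if name not in _STAGES:
            raise ValueError(f"unknown stage {name!r}")
        try:
            _STAGES[name](config["stages"][name], stage_seeds[name], out, echo, comparisons)
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            failures[name] = f"{type(exc).__name__}: {exc}"
            if not keep_going:
                raise

    stat_rows = []
    for measure, by_group in comparisons:
        if len(by_group) < 2 or any(len(v) < 3 for v in by_group.values()):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comp = choose_and_test(by_group, policy, measure=measure)
        stat_rows.extend(_comparison_rows(comp))
    if stat_rows:
        _write(pd.DataFrame(stat_rows), out / "group_comparisons.csv")

    echo["stage_seeds"] = stage_seeds
    echo["failures"] = failures
    with open(out / "methods_echo.json", "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True)
    return {"out_dir": str(out), "failures": failures,
            "n_comparisons": len(stat_rows), "echo": echo}
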