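"""End-to-end study analysis: behavior, ERP, oscillations, networks, stats.

``run_study`` executes the full analysis on a (synthetic or supplied)
five-group pre/post study and emits a structured report: per-group
behavioral tables (reaction time, d', change index X) with ANOVA and
Bonferroni-corrected pairwise tests; within-group pre/post cluster-based
permutation tests on ERP waveforms and on band-averaged oscillatory power;
between-group tests on the post-minus-pre difference maps; resting-state
PLV network metrics with paired tests and FDR correction; and Pearson
correlations between the electrophysiological and behavioral changes.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import behavior as bhv
from . import connectivity as con
from . import erp as erp_mod
from . import stats as st
from . import timefreq as tf
from .bands import DEFAULT_BANDS, BandDefinition
from .synth import GROUPS, SimConfig, StudyDataset, generate_study

__all__ = ["StudyConfig", "StudyReport", "run_study", "correlate_outcomes",
           "config_to_dict", "config_from_dict"]


@dataclass(frozen=True)
class StudyConfig:
    """Analysis parameters for one study run (defaults match the methods)."""

    sim: SimConfig = field(default_factory=SimConfig)
    groups: tuple[str, ...] = GROUPS
    reference_group: str = "sham"
    n_permutations: int = 1000
    cluster_alpha: float = 0.05   # cluster-forming threshold (uncorrected)
    alpha: float = 0.025          # per-tail cluster significance
    density: float = 0.30
    network_bands: tuple[str, ...] = ("theta", "alpha", "beta1")
    power_bands: tuple[str, ...] = ("theta", "alpha", "beta1", "beta2", "gamma")
    tfr_freqs: np.ndarray | None = None  # None -> 3..80 Hz in 0.5 Hz steps
    power_window: tuple[float, float] = (0.05, 0.35)
    cluster_decim: int = 10       # ERP time decimation for the cluster tests
    erp_channels: tuple[str, ...] = ("FC1", "FCz", "FC2")
    preprocess: bool = False      # synthetic data are clean by construction
    include_rest: bool = True
    seed: int = 0

    def band(self, name: str) -> BandDefinition:
        return DEFAULT_BANDS[name]


def config_to_dict(cfg: StudyConfig) -> dict:
    """JSON-serializable form of a study config (round-trips exactly)."""
    d = dataclasses.asdict(cfg)
    if d["tfr_freqs"] is not None:
        d["tfr_freqs"] = list(np.asarray(d["tfr_freqs"], float))
    return d


def config_from_dict(d: dict) -> StudyConfig:
    from .synth import ERPComponent, EffectDelta
    d = dict(d)
    sim = dict(d.pop("sim"))
    sim["erp_components"] = tuple(
        ERPComponent(**c) for c in sim["erp_components"])
    sim["effect_deltas"] = {
        g: EffectDelta(**v) for g, v in sim["effect_deltas"].items()}
    sim["coupled_pairs"] = tuple(tuple(p) for p in sim["coupled_pairs"])
    freqs = d.pop("tfr_freqs")
    for key in ("groups", "network_bands", "power_bands", "erp_channels"):
        d[key] = tuple(d[key])
    for key in ("power_window",):
        d[key] = tuple(d[key])
    return StudyConfig(
        sim=SimConfig(**sim),
        tfr_freqs=None if freqs is None else np.asarray(freqs, float), **d)


@dataclass
class StudyReport:
    behavioral: pd.DataFrame
    behavioral_tests: dict
    erp_components: pd.DataFrame
    erp_cluster_tests: dict
    power: pd.DataFrame
    power_cluster_tests: dict
    network: pd.DataFrame
    network_tests: pd.DataFrame | None
    correlations: pd.DataFrame
    manifest: dict

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)
        payload = {
            "behavioral": self.behavioral,
            "behavioral_tests": self.behavioral_tests,
            "erp_components": self.erp_components,
            "erp_cluster_tests": self.erp_cluster_tests,
            "power": self.power,
            "power_cluster_tests": self.power_cluster_tests,
            "network": self.network,
            "network_tests": self.network_tests,
            "correlations": self.correlations,
            "manifest": self.manifest,
        }
        return json.dumps(payload, default=default, indent=2)

    def to_markdown(self) -> str:
        lines = ["# Study report", "", "## Behavioral (group means)", ""]
        g = (self.behavioral.groupby(["group", "session"])
             [["mean_rt", "dprime"]].mean().reset_index())
        lines.append(g.to_string(index=False))
        lines += ["", "## Significant ERP clusters"]
        for key, res in self.erp_cluster_tests.items():
            for c in res.get("significant", []):
                lines.append(f"- {key}: mass={c['mass']:.1f} p={c['pvalue']:.4f}")
        lines += ["", "## Significant power clusters"]
        for key, res in self.power_cluster_tests.items():
            for c in res.get("significant", []):
                lines.append(f"- {key}: mass={c['mass']:.1f} p={c['pvalue']:.4f}")
        if self.network_tests is not None and len(self.network_tests):
            lines += ["", "## Network pre/post tests", "",
                      self.network_tests.to_string(index=False)]
        if len(self.correlations):
            lines += ["", "## Correlations", "",
                      self.correlations.to_string(index=False)]
        return "\n".join(lines)


def _cluster_summary(res: st.ClusterStatResult) -> dict:
    return {
        "n_clusters": len(res.clusters),
        "n_permutations": res.n_permutations,
        "alpha": res.alpha,
        "seed": res.seed,
        "clusters": [
            {"mass": c.mass, "pvalue": c.pvalue, "tail": c.tail,
             "n_channels": len(c.channels), "n_points": len(c.points)}
            for c in res.clusters
        ],
        "significant": [
            {"mass": c.mass, "pvalue": c.pvalue, "tail": c.tail,
             "channels": list(c.channels), "time_indices": list(c.time_indices)}
            for c in res.significant()
        ],
    }


def _gated_group_comparison(values: dict[str, np.ndarray], reference: str) -> dict:
    method = "anova" if st.normality_gate(values) == "parametric" else "kruskal"
    res = bhv.compare_groups(values, method=method, reference=reference)
    return {
        "method": res.method, "statistic": res.statistic, "df": res.df,
        "pvalue": res.pvalue, "pairwise_vs_reference": res.pairwise_vs_reference,
    }


def _paired_test(pre: np.ndarray, post: np.ndarray) -> tuple[str, float, float]:
    """Normality-gated paired test on post-pre; returns (method, stat, p)."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    if np.allclose(d, 0):
        return "ttest_rel", 0.0, 1.0
    if sps.shapiro(d).pvalue < 0.05:
        stat, p = sps.wilcoxon(d)
        return "wilcoxon", float(stat), float(p)
    stat, p = sps.ttest_rel(post, pre)
    return "ttest_rel", float(stat), float(p)


def run_study(cfg: StudyConfig, data: StudyDataset | None = None) -> StudyReport:
    """Run the complete analysis and return the structured report."""
    if data is None:
        data = generate_study(cfg.sim, groups=cfg.groups,
                              include_rest=cfg.include_rest)
    montage = data.montage
    adjacency = st.channel_adjacency(montage)
    seeds = np.random.SeedSequence(cfg.seed)
    next_seed = iter(s.generate_state(1)[0] % (2**31) for s in seeds.spawn(4096))
    manifest = {
        "seed": cfg.seed, "groups": list(cfg.groups),
        "n_subjects": len(data.subjects),
        "n_permutations": cfg.n_permutations,
        "montage_channels": list(montage.ch_names),
        "stages": [],
    }

    # ---- behavior ---------------------------------------------------------
    rows = []
    for sub in data.subjects:
        pre = bhv.summarize_session(sub.behavior["pre"])
        post = bhv.summarize_session(sub.behavior["post"])
        x = bhv.change_index(pre.mean_rt, post.mean_rt)
        rows.append({"subject": sub.subject_id, "group": sub.group,
                     "session": "pre", "mean_rt": pre.mean_rt,
                     "dprime": pre.dprime, "x": np.nan})
        rows.append({"subject": sub.subject_id, "group": sub.group,
                     "session": "post", "mean_rt": post.mean_rt,
                     "dprime": post.dprime, "x": x.x})
    behavioral = pd.DataFrame(rows)
    wide = behavioral.pivot_table(index=["subject", "group"], columns="session",
                                  values="mean_rt").reset_index()
    wide["diff"] = wide["pre"] - wide["post"]
    wide["x"] = wide["diff"] / wide["pre"]
    behavioral_tests = {}
    for quantity in ("pre", "post", "diff", "x"):
        vals = {g: wide.loc[wide["group"] == g, quantity].to_numpy()
                for g in cfg.groups}
        behavioral_tests[quantity] = _gated_group_comparison(
            vals, cfg.reference_group)
    manifest["stages"].append({"stage": "behavior", "n_rows": len(behavioral)})

    # ---- ERP --------------------------------------------------------------
    erps: dict[tuple[str, str], list[erp_mod.ERPWaveform]] = {}
    comp_rows = []
    for sub in data.subjects:
        for session in ("pre", "post"):
            ep = sub.task[session]
            if cfg.preprocess:
                ep, _ = erp_mod.preprocess(ep)
            w = erp_mod.average_erp(ep)
            erps.setdefault((sub.group, session), []).append(w)
            for comp in erp_mod.COMPONENT_WINDOWS.values():
                comp_rows.append({
                    "subject": sub.subject_id, "group": sub.group,
                    "session": session, "component": comp.label,
                    "amplitude_uv": erp_mod.component_amplitude(
                        w, comp, cfg.erp_channels),
                })
    erp_components = pd.DataFrame(comp_rows)

    decim = max(1, cfg.cluster_decim)
    def stack(waves):  # subjects x channels x times (decimated)
        return np.stack([w.data[:, ::decim] for w in waves])

    erp_cluster_tests = {}
    for g in cfg.groups:
        res = st.cluster_permutation_test(
            stack(erps[(g, "post")]), stack(erps[(g, "pre")]),
            adjacency, paired=True, n_permutations=cfg.n_permutations,
            cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha,
            seed=int(next(next_seed)))
        erp_cluster_tests[f"{g}:post-vs-pre"] = _cluster_summary(res)
    ref = cfg.reference_group
    ref_delta = stack(erps[(ref, "post")]) - stack(erps[(ref, "pre")])
    for g in cfg.groups:
        if g == ref:
            continue
        delta = stack(erps[(g, "post")]) - stack(erps[(g, "pre")])
        res = st.cluster_permutation_test(
            delta, ref_delta, adjacency, paired=False,
            n_permutations=cfg.n_permutations,
            cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha,
            seed=int(next(next_seed)))
        erp_cluster_tests[f"{g}-vs-{ref}:delta"] = _cluster_summary(res)

    # group comparison of the fronto-central Delta component amplitudes
    comp_wide = erp_components.pivot_table(
        index=["subject", "group", "component"], columns="session",
        values="amplitude_uv").reset_index()
    comp_wide["delta"] = comp_wide["post"] - comp_wide["pre"]
    for comp in erp_mod.COMPONENT_WINDOWS:
        sel = comp_wide[comp_wide["component"] == comp]
        vals = {g: sel.loc[sel["group"] == g, "delta"].to_numpy()
                for g in cfg.groups}
        test = _gated_group_comparison(vals, ref)
        pair = test["pairwise_vs_reference"]
        if pair:  # report FDR-corrected pairwise decisions as well
            names = list(pair)
            raw = np.minimum(1.0, np.array([pair[k] for k in names]))
            test["fdr_reject_vs_reference"] = dict(
                zip(names, st.fdr_bh(raw).tolist()))
        erp_cluster_tests[f"anova:delta_{comp}"] = test
    manifest["stages"].append({"stage": "erp", "decim": decim})

    # ---- time-frequency ---------------------------------------------------
    freqs = (tf.default_freq_grid() if cfg.tfr_freqs is None
             else np.asarray(cfg.tfr_freqs, float))
    band_maps: dict[tuple[str, str, str], list[np.ndarray]] = {}
    power_rows = []
    active_bands = [b for b in cfg.power_bands
                    if DEFAULT_BANDS[b].mask(freqs).any()]
    fc_idx = montage.index(cfg.erp_channels)
    for sub in data.subjects:
        for session in ("pre", "post"):
            tfr = tf.baseline_db(tf.spectrogram_hanning(
                sub.task[session], freqs=freqs))
            for bname in active_bands:
                per_ch = tf.band_average(tfr, cfg.band(bname), cfg.power_window)
                band_maps.setdefault((sub.group, session, bname), []).append(per_ch)
                power_rows.append({
                    "subject": sub.subject_id, "group": sub.group,
                    "session": session, "band": bname,
                    "power_db": float(per_ch[fc_idx].mean()),
                })
    power = pd.DataFrame(power_rows)

    power_cluster_tests = {}
    for bname in active_bands:
        for g in cfg.groups:
            a = np.stack(band_maps[(g, "post", bname)])[:, :, None]
            b = np.stack(band_maps[(g, "pre", bname)])[:, :, None]
            res = st.cluster_permutation_test(
                a, b, adjacency, paired=True,
                n_permutations=cfg.n_permutations,
                cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha,
                seed=int(next(next_seed)))
            power_cluster_tests[f"{g}:{bname}:post-vs-pre"] = _cluster_summary(res)
        ref_d = (np.stack(band_maps[(ref, "post", bname)])
                 - np.stack(band_maps[(ref, "pre", bname)]))[:, :, None]
        for g in cfg.groups:
            if g == ref:
                continue
            d = (np.stack(band_maps[(g, "post", bname)])
                 - np.stack(band_maps[(g, "pre", bname)]))[:, :, None]
            res = st.cluster_permutation_test(
                d, ref_d, adjacency, paired=False,
                n_permutations=cfg.n_permutations,
                cluster_alpha=cfg.cluster_alpha, alpha=cfg.alpha,
                seed=int(next(next_seed)))
            power_cluster_tests[f"{g}-vs-{ref}:{bname}:delta"] = _cluster_summary(res)
    pw = power.pivot_table(index=["subject", "group", "band"], columns="session",
                           values="power_db").reset_index()
    pw["delta"] = pw["post"] - pw["pre"]
    for bname in active_bands:
        sel = pw[pw["band"] == bname]
        vals = {g: sel.loc[sel["group"] == g, "delta"].to_numpy()
                for g in cfg.groups}
        power_cluster_tests[f"anova:delta_{bname}"] = _gated_group_comparison(
            vals, ref)
    manifest["stages"].append({"stage": "timefreq", "n_freqs": int(freqs.size),
                               "bands": active_bands})

    # ---- resting-state networks ------------------------------------------
    net_rows = []
    have_rest = all(sub.rest for sub in data.subjects)
    if cfg.include_rest and have_rest:
        for sub in data.subjects:
            for session in ("pre", "post"):
                for bname in cfg.network_bands:
                    m = con.band_plv(sub.rest[session], cfg.band(bname))
                    g = con.proportional_threshold(m, cfg.density)
                    gm = con.graph_metrics(g)
                    net_rows.append({
                        "subject": sub.subject_id, "group": sub.group,
                        "session": session, "band": bname,
                        "mean_plv": m.mean_plv(), "cp": gm.cp, "lp": gm.lp,
                        "eglob": gm.eglob, "eloc": gm.eloc_mean,
                    })
    network = pd.DataFrame(net_rows)
    network_tests = None
    if len(network):
        test_rows = []
        for g in cfg.groups:
            for bname in cfg.network_bands:
                sel = network[(network["group"] == g) & (network["band"] == bname)]
                w = sel.pivot_table(
                    index="subject", columns="session",
                    values=["mean_plv", "cp", "lp", "eglob", "eloc"])
                for metric in ("mean_plv", "cp", "lp", "eglob", "eloc"):
                    method, stat, p = _paired_test(
                        w[(metric, "pre")].to_numpy(),
                        w[(metric, "post")].to_numpy())
                    test_rows.append({
                        "group": g, "band": bname, "metric": metric,
                        "method": method, "statistic": stat, "pvalue": p,
                        "direction": float(np.mean(w[(metric, "post")]
                                                   - w[(metric, "pre")])),
                    })
        network_tests = pd.DataFrame(test_rows)
        # FDR across metrics and bands within each group
        network_tests["fdr_reject"] = False
        for g in cfg.groups:
            rows_g = network_tests["group"] == g
            network_tests.loc[rows_g, "fdr_reject"] = st.fdr_bh(
                network_tests.loc[rows_g, "pvalue"].to_numpy())
    manifest["stages"].append({"stage": "connectivity",
                               "n_rows": len(network)})

    # ---- correlations -----------------------------------------------------
    correlations = correlate_outcomes(
        comp_wide, pw, wide, groups=cfg.groups)
    manifest["stages"].append({"stage": "correlations",
                               "n_rows": len(correlations)})

    return StudyReport(
        behavioral=behavioral, behavioral_tests=behavioral_tests,
        erp_components=erp_components, erp_cluster_tests=erp_cluster_tests,
        power=power, power_cluster_tests=power_cluster_tests,
        network=network, network_tests=network_tests,
        correlations=correlations, manifest=manifest)


def correlate_outcomes(comp_deltas: pd.DataFrame, power_deltas: pd.DataFrame,
                       rt_deltas: pd.DataFrame, *,
                       groups: tuple[str, ...]) -> pd.DataFrame:
    """Pearson correlations between per-subject changes, per group.

    Pairs: each (Delta component, Delta RT), each (Delta band power,
    Delta RT) and each (Delta component, Delta band power).  Delta RT is
    post - pre in seconds, so an amplitude increase that speeds subjects up
    appears as a negative correlation.  Groups with fewer than 3 subjects,
    or zero-variance columns, are skipped.
    """
    rows = []
    rt = rt_deltas.set_index("subject")
    for g in groups:
        subs = rt.index[rt["group"] == g]
        if len(subs) < 3:
            continue
        drt = -(rt.loc[subs, "diff"])  # post - pre (negative = faster)
        series = {}
        for comp, sel in comp_deltas[comp_deltas["group"] == g].groupby("component"):
            series[f"d_{comp}"] = sel.set_index("subject").loc[subs, "delta"]
        for band, sel in power_deltas[power_deltas["group"] == g].groupby("band"):
            series[f"d_{band}"] = sel.set_index("subject").loc[subs, "delta"]
        pairs = [(k, "d_rt") for k in series]
        comp_keys = [k for k in series if k[2:] in
                     ("N100", "P150", "N200", "P300")]
        band_keys = [k for k in series if k not in comp_keys]
        pairs += [(c, b) for c in comp_keys for b in band_keys]
        series["d_rt"] = drt
        for xk, yk in pairs:
            x, y = series[xk].to_numpy(), series[yk].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r, p = st.pearson_corr(x, y)
            rows.append({"group": g, "x": xk, "y": yk, "r": r, "pvalue": p,
                         "n": len(x)})
    return pd.DataFrame(rows, columns=["group", "x", "y", "r", "pvalue", "n"])
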