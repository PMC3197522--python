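"""End-to-end orchestration: simulate → preprocess → spectral → graph →
null model → statistics, from a single config, into one results bundle.

The bundle mirrors the analysis' natural outputs: a long metrics table
over the 18-value threshold sweep, a per-network summary at the
conservative analysis threshold (with γ/λ/σ against the 30-member rewired
ensemble), spectral summaries, the cross-network correlation matrix, the
node-equalized replication, and the statistical report.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graph as gr
from . import nullmodel as nm
from . import spectral as sp
from . import stats as st
from .preprocess import exclude_overlap, preprocess_subject
from .simulate import (DEFAULT_BAND, GeneratorConfig, RSNAtlas,
                       generate_atlas, generate_cohort)

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline"]

log = logging.getLogger(__name__)

GROUP_METRICS = ("C", "L", "gamma", "lambda", "sigma",
                 "band_contribution", "falff")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    band: tuple[float, float] = DEFAULT_BAND
    spectrum_ceiling: float = 0.25
    analysis_threshold_rule: str = "bonferroni_auto"   # or "fixed"
    fixed_threshold: float | None = None
    n_null: int = 30
    equalize: bool = True
    n_equalize_draws: int = 10
    smooth_fwhm_mm: float = 0.0
    absolute_r: bool = False
    falff_mode: str = "power"
    seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        low, high = self.band
        if not 0 < low < high <= self.spectrum_ceiling:
            raise PipelineError("band must lie within (0, spectrum_ceiling]")
        grid = gr.threshold_grid()
        if len(grid) != 18:
            raise PipelineError("threshold grid must have 18 values")
        if self.analysis_threshold_rule not in ("bonferroni_auto", "fixed"):
            raise PipelineError("unknown analysis_threshold_rule")
        if self.analysis_threshold_rule == "fixed" and self.fixed_threshold is None:
            raise PipelineError("fixed rule requires fixed_threshold")
        if self.n_null < 1:
            raise PipelineError("n_null must be ≥ 1")


@dataclass
class ResultsBundle:
    metrics_by_threshold: pd.DataFrame
    metrics_at_analysis_threshold: pd.DataFrame
    equalized_metrics: pd.DataFrame | None
    spectral_table: pd.DataFrame
    cross_rsn: sp.RSNCrossCorrelation
    stats_report: pd.DataFrame
    analysis_threshold: float
    provenance: dict


def _sub_seed(root: int, *key: int) -> int:
    return int(np.random.SeedSequence([root, *key]).generate_state(1)[0] % (2**31))


def _network_row(corr: gr.CorrelationMatrix, T: float, absolute: bool):
    g = gr.threshold_graph(corr, T, absolute=absolute)
    m = gr.graph_metrics(g)
    return g, m


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Run the full analysis on a freshly generated synthetic cohort.

    Deterministic for a fixed config: generation uses
    ``config.generator.seed``; equalization and rewiring use named
    substreams of ``config.seed``.
    """
    config.validate()
    t0 = time.time()
    gen = config.generator
    atlas = generate_atlas(gen)
    cohort = generate_cohort(gen, atlas)
    exclusive = exclude_overlap(atlas)
    names = [n.name for n in gen.networks]
    groups = {n.name: n.group for n in gen.networks}
    grid = gr.threshold_grid()
    df = gen.n_timepoints - 2

    # analysis threshold: Bonferroni over the voxel pairs of the largest
    # network (post-exclusion), df = t − 2
    largest = max(len(v) for v in exclusive.values())
    if config.analysis_threshold_rule == "fixed":
        t_star = float(config.fixed_threshold)
    else:
        n_pairs = largest * (largest - 1) // 2
        t_star = gr.analysis_threshold(n_pairs, df)
    log.info("analysis threshold T* = %.3f (largest network %d voxels)",
             t_star, largest)

    sweep_rows, star_rows, spec_rows = [], [], []
    mean_tcs: list[dict[str, np.ndarray]] = []
    corrs: dict[tuple[str, str], gr.CorrelationMatrix] = {}

    for ds in cohort:
        filtered, regressed = preprocess_subject(
            ds, atlas, smooth_fwhm_mm=config.smooth_fwhm_mm,
            voxel_size_mm=gen.voxel_size_mm, band=config.band,
            exclusive=exclusive,
        )
        mean_tcs.append({n: filtered[n].mean_timecourse() for n in names})
        for name in names:
            summ = sp.band_power_summary(regressed[name], config.band,
                                         falff_mode=config.falff_mode)
            spec_rows.append(dict(
                subject=ds.subject_id, network=name, group=groups[name],
                band_contribution=summ.band_contribution, falff=summ.falff,
            ))
            corr = gr.correlation_matrix(filtered[name])
            corrs[(ds.subject_id, name)] = corr
            for T in grid:
                g, m = _network_row(corr, float(T), config.absolute_r)
                sweep_rows.append(dict(
                    subject=ds.subject_id, network=name, group=groups[name],
                    T=float(T), N=m.n_nodes, E=m.n_edges, C=m.clustering,
                    L=m.path_length,
                    lcc_fraction=m.largest_component_fraction,
                ))

    # small-world indices at the analysis threshold
    for si, ds in enumerate(cohort):
        for ni, name in enumerate(names):
            corr = corrs[(ds.subject_id, name)]
            g, m = _network_row(corr, t_star, config.absolute_r)
            sw, ens = nm.small_world_indices(
                g, m=config.n_null, metrics=m,
                seed=_sub_seed(config.seed, 23, si, ni))
            star_rows.append(dict(
                subject=ds.subject_id, network=name, group=groups[name],
                T=t_star, N=m.n_nodes, E=m.n_edges, C=m.clustering,
                L=m.path_length, lcc_fraction=m.largest_component_fraction,
                c_rand=ens.c_rand, l_rand=ens.l_rand,
                gamma=sw.gamma, **{"lambda": sw.lam}, sigma=sw.sigma,
            ))

    metrics_star = pd.DataFrame(star_rows)
    spectral_table = pd.DataFrame(spec_rows)
    cross = sp.rsn_cross_correlation(mean_tcs, networks=names)

    equalized = None
    if config.equalize:
        equalized = _equalized_metrics(config, cohort, exclusive, corrs,
                                       names, groups, t_star)

    report = _stats_report(metrics_star, spectral_table, equalized,
                           groups, names)

    bundle = ResultsBundle(
        metrics_by_threshold=pd.DataFrame(sweep_rows),
        metrics_at_analysis_threshold=metrics_star,
        equalized_metrics=equalized,
        spectral_table=spectral_table,
        cross_rsn=cross,
        stats_report=report,
        analysis_threshold=t_star,
        provenance=dict(
            config=dataclasses.asdict(config),
            analysis_threshold=t_star,
            largest_network_voxels=largest,
            df=df,
            elapsed_s=round(time.time() - t0, 2),
        ),
    )
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return bundle


def _equalized_metrics(config, cohort, exclusive, corrs, names, groups,
                       t_star) -> pd.DataFrame:
    """Node-equalized replication: every network subsampled to the
    smallest network's size, ``n_equalize_draws`` seeded draws, metrics
    averaged over draws per subject × network."""
    index_sets = {n: np.arange(len(exclusive[n])) for n in names}
    draws = gr.equalize_nodes(index_sets,
                              seed=_sub_seed(config.seed, 31),
                              n_draws=config.n_equalize_draws)
    rows = []
    for si, ds in enumerate(cohort):
        for ni, name in enumerate(names):
            corr = corrs[(ds.subject_id, name)]
            acc: dict[str, list[float]] = {k: [] for k in
                                           ("N", "E", "C", "L",
                                            "lcc_fraction", "gamma",
                                            "lambda", "sigma")}
            for di, draw in enumerate(draws):
                idx = draw[name]
                sub = gr.CorrelationMatrix(
                    network=name, subject_id=ds.subject_id,
                    r=corr.r[np.ix_(idx, idx)],
                    n_timepoints=corr.n_timepoints)
                g, m = _network_row(sub, t_star, config.absolute_r)
                sw, _ = nm.small_world_indices(
                    g, m=config.n_null, metrics=m,
                    seed=_sub_seed(config.seed, 37, si, ni, di))
                acc["N"].append(m.n_nodes)
                acc["E"].append(m.n_edges)
                acc["C"].append(m.clustering)
                acc["L"].append(m.path_length)
                acc["lcc_fraction"].append(m.largest_component_fraction)
                acc["gamma"].append(sw.gamma)
                acc["lambda"].append(sw.lam)
                acc["sigma"].append(sw.sigma)
            rows.append(dict(
                subject=ds.subject_id, network=name, group=groups[name],
                T=t_star, n_draws=len(draws),
                **{k: float(np.mean(v)) for k, v in acc.items()},
            ))
    return pd.DataFrame(rows)


def _wide(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    return table.pivot(index="subject", columns="network", values=metric)


def _stats_report(metrics_star, spectral_table, equalized, groups,
                  names) -> pd.DataFrame:
    """Assemble the tidy statistics table: per-network one-sample tests of
    γ/λ/σ against 1, one-way ANOVA across networks and two-way group
    ANOVA per metric (Bonferroni family = number of metrics)."""
    merged = metrics_star.merge(
        spectral_table, on=("subject", "network", "group"))
    rows = []
    unity_family = 3 * len(names)
    for metric in ("gamma", "lambda", "sigma"):
        for name in names:
            vals = merged.loc[merged.network == name, metric]
            res = st.test_vs_unity(vals, family=unity_family)
            rows.append(dict(
                metric=metric, scope="vs_unity", network=name,
                group=groups[name], statistic=res.t, p_raw=res.p_raw,
                p_corrected=res.p_corrected, family=res.family,
                mean=float(vals.mean()), sd=float(vals.std(ddof=1)),
            ))
    family = len(GROUP_METRICS)
    for metric in GROUP_METRICS:
        wide = _wide(merged, metric)
        f1, p1 = st.anova_networks(wide)
        rows.append(dict(metric=metric, scope="anova_networks",
                         statistic=f1, p_raw=p1))
        res = st.anova_groups(wide, groups, family=family)
        cog = merged.loc[merged.group == "cognitive", metric].mean()
        per = merged.loc[merged.group == "perceptual", metric].mean()
        rows.append(dict(
            metric=metric, scope="anova_groups", statistic=res.f,
            p_raw=res.p_raw, p_corrected=res.p_corrected, family=res.family,
            mean_cognitive=float(cog), mean_perceptual=float(per),
        ))
    if equalized is not None:
        for metric in ("C", "L", "gamma", "lambda", "sigma"):
            wide = _wide(equalized, metric)
            res = st.anova_groups(wide, groups, family=5)
            cog = equalized.loc[equalized.group == "cognitive", metric].mean()
            per = equalized.loc[equalized.group == "perceptual", metric].mean()
            rows.append(dict(
                metric=metric, scope="anova_groups_equalized",
                statistic=res.f, p_raw=res.p_raw,
                p_corrected=res.p_corrected, family=res.family,
                mean_cognitive=float(cog), mean_perceptual=float(per),
            ))
    return pd.DataFrame(rows)
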