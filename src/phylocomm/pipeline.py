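"""End-to-end orchestration: synthetic study → preprocessing → phylogenetic
signals → co-occurrence networks → group statistics.

One master seed drives every stage through spawned ``SeedSequence`` children,
so a run is reproducible bit-for-bit (the log file records wall-clock times
and is the only non-deterministic output). All result tables are TSV with a
leading ``# config_sha256=...`` provenance line and the full configuration is
echoed to ``config.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import phylo, preprocess, stats, synth, topology
from .cooccurrence import c_score_null_test, sparcc_pvalues

log = logging.getLogger(__name__)

PANEL_VARS = ["pH", "SOC", "TN", "AK", "AP", "Ivt", "MC",
              "richness", "alpha_mpd", "alpha_nri"]
CALORIMETRY_VARS = ["P_max", "t_max", "Q_T", "K",
                    "richness", "alpha_mpd", "alpha_nri"]


@dataclass
class RunConfig:
    """Pipeline settings. Defaults are the full-fidelity analysis settings;
    :meth:`fast` returns a scaled-down profile for desk-scale runs."""

    # inputs: either paths, or a synthetic design
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    synth_n_tips: int = 500
    synth_n_taxa_community: int = 120

    depth: int = 7000
    n_rand: int = 1000
    correlogram_classes: int = 100
    correlogram_perms: int = 999
    top_k: int = 500
    sparcc_perms: int = 999          # the source analysis used 9,999
    sparcc_inner_iters: int = 20
    sparcc_perm_inner_iters: int = 20
    cscore_nulls: int = 1000
    rho_thresh: float = 0.85
    p_thresh: float = 0.01
    env_var: str = "AP"
    seed: int = 0
    skip_network: bool = False

    @classmethod
    def fast(cls, **overrides) -> "RunConfig":
        """Scaled-down permutation counts for quick, deterministic runs."""
        # 199 SparCC permutations keep the minimum pseudo-p (1/200) below
        # the default p < 0.01 edge threshold
        base = dict(n_rand=99, correlogram_perms=99, sparcc_perms=199,
                    sparcc_perm_inner_iters=5, cscore_nulls=199)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def sha256(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from JSON or YAML."""
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig(**data)


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig,
                 index: bool = True, float_format: str = "%.6g") -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={config.sha256}\n")
        df.to_csv(fh, sep="\t", index=index, float_format=float_format)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _group_table(rarefied_table, members, top_k):
    """Per-group subtable: drop OTUs absent from the group, keep top-k."""
    gtable = rarefied_table.subset(samples=members)
    present = gtable.data.columns[(gtable.data > 0).any(axis=0)]
    gtable = pio.OtuTable(gtable.data[present].copy())
    return preprocess.top_k_otus(gtable, top_k)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage; returns the results directory.

    Emits: config.json, otu_table/tree/metadata (when synthesized),
    alpha.tsv, beta_pairs.tsv, beta_groups.tsv, ttests.tsv, correlogram.tsv,
    letters.tsv, panel.tsv, calorimetry_panel.tsv, quad.tsv, cscore.tsv and,
    unless ``skip_network``, per-group rho/p matrices, GraphML + edge lists
    and topology.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("phylocomm")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    try:
        _run(config, outdir)
    finally:
        log.info("pipeline finished in %.1f s", time.time() - t0)
        root.removeHandler(handler)
        handler.close()
    return outdir


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %-12s done in %6.1f s", name, time.time() - t0)
            return result
        return inner
    return wrap


def _run(config: RunConfig, outdir: Path) -> None:
    with open(outdir / "config.json", "w") as fh:
        json.dump({"config": config.to_dict(), "sha256": config.sha256},
                  fh, indent=2, sort_keys=True)
    ss = np.random.SeedSequence(config.seed)
    (s_synth, s_rarefy, s_alpha, s_beta, s_correlo, s_net,
     s_cscore, s_topo) = ss.spawn(8)

    # ---- inputs -----------------------------------------------------------
    @_stage("inputs")
    def load():
        if config.table_path:
            table = pio.read_otu_table(config.table_path)
            tree = pio.read_tree_newick(config.tree_path)
            metadata = pio.read_metadata(config.metadata_path)
            metadata.check_covers(table)
            return table, tree, metadata
        study = synth.make_study(n_tips=config.synth_n_tips,
                                 n_taxa_community=config.synth_n_taxa_community,
                                 seed=s_synth)
        study.write(outdir / "synthetic_study")
        return study.table, study.tree, study.metadata

    table, tree, metadata = load()

    # ---- preprocess -------------------------------------------------------
    @_stage("rarefy")
    def do_rarefy():
        return preprocess.rarefy(table, config.depth, seed=s_rarefy)

    rarefied = do_rarefy()
    f_matrix = preprocess.relative_abundance(rarefied.table)
    dm = phylo.cophenetic_distances(tree)
    keep = [o for o in f_matrix.columns if o in set(dm.ids)]
    if len(keep) < f_matrix.shape[1]:
        log.warning("%d OTUs missing from the tree dropped",
                    f_matrix.shape[1] - len(keep))
        f_matrix = f_matrix[keep]

    groups = metadata.groups.loc[f_matrix.index]

    # ---- alpha phylogenetic structure ------------------------------------
    @_stage("alpha")
    def do_alpha():
        res = phylo.alpha_nri_table(f_matrix, dm, n_rand=config.n_rand,
                                    seed=s_alpha)
        res.insert(0, "group", groups)
        _write_table(res, outdir / "alpha.tsv", config)
        return res

    alpha = do_alpha()

    # ---- beta within groups ----------------------------------------------
    @_stage("beta")
    def do_beta():
        pairs = []
        for g in pd.unique(groups):
            members = list(groups[groups == g].index)
            pairs += [(a, b) for i, a in enumerate(members)
                      for b in members[i + 1:]]
        res = phylo.beta_nri_pairs(f_matrix, dm, pairs=pairs,
                                   n_rand=config.n_rand, seed=s_beta)
        _write_table(res, outdir / "beta_pairs.tsv", config, index=False)
        gmeans = phylo.group_mean_beta(res, metadata, "beta_mpd_observed")
        gnri = phylo.group_mean_beta(res, metadata, "beta_nri")
        gmeans = gmeans.merge(gnri, on=["group", "n_pairs"],
                              suffixes=("_beta_mpd", "_beta_nri"))
        _write_table(gmeans, outdir / "beta_groups.tsv", config, index=False)
        return res

    beta = do_beta()

    # ---- t-tests against the ±2 decision bands ---------------------------
    @_stage("ttests")
    def do_ttests():
        rows = []
        nri_vals = alpha["alpha_nri"].dropna()
        t_a = stats.ttest_vs_threshold(nri_vals, 2.0)
        rows.append({"metric": "alpha_nri", "threshold": 2.0, "t": t_a.t,
                     "p": t_a.p, "mean": t_a.mean, "verdict": t_a.verdict})
        bn = beta["beta_nri"].dropna()
        if len(bn) >= 2:
            t_b = stats.ttest_vs_threshold(bn, -2.0)
            rows.append({"metric": "beta_nri", "threshold": -2.0, "t": t_b.t,
                         "p": t_b.p, "mean": t_b.mean, "verdict": t_b.verdict})
        df = pd.DataFrame(rows)
        _write_table(df, outdir / "ttests.tsv", config, index=False)
        return df

    do_ttests()

    # ---- phylogenetic signal (Mantel correlogram) ------------------------
    @_stage("correlogram")
    def do_correlogram():
        env = metadata.covariates[config.env_var].loc[f_matrix.index]
        optima = phylo.environmental_optimum(f_matrix, env)
        sub = dm.loc(list(optima.index))
        dphy = phylo.DistanceMatrix(ids=tuple(optima.index), values=sub)
        dopt = phylo.trait_distance_matrix(optima)
        classes = phylo.mantel_correlogram(
            dphy, dopt, n_classes=config.correlogram_classes,
            n_perm=config.correlogram_perms, seed=s_correlo)
        df = phylo.correlogram_frame(classes)
        _write_table(df, outdir / "correlogram.tsv", config, index=False)
        return df

    do_correlogram()

    # ---- per-group networks ----------------------------------------------
    if not config.skip_network:
        (outdir / "networks").mkdir(exist_ok=True)

        @_stage("networks")
        def do_networks():
            records = []
            net_seeds = s_net.spawn(len(pd.unique(groups)))
            topo_base = int(np.random.default_rng(s_topo).integers(2 ** 31))
            for g, gseed in zip(pd.unique(groups), net_seeds):
                members = list(groups[groups == g].index)
                gtable = _group_table(rarefied.table, members, config.top_k)
                res = sparcc_pvalues(
                    gtable, n_perm=config.sparcc_perms, seed=gseed,
                    inner_iters=config.sparcc_inner_iters,
                    perm_inner_iters=config.sparcc_perm_inner_iters)
                _write_table(res.rho_frame, outdir / "networks" / f"{g}_rho.tsv",
                             config, float_format="%.4f")
                _write_table(res.pval_frame, outdir / "networks" / f"{g}_p.tsv",
                             config, float_format="%.4g")
                net = topology.build_network(res, config.rho_thresh,
                                             config.p_thresh)
                pio.write_network_graphml(net, outdir / "networks" / f"{g}.graphml")
                pio.write_edge_list(net, outdir / "networks" / f"{g}_edges.tsv")
                records.append(topology.topology_metrics(net, seed=topo_base,
                                                         name=str(g)))
            ranked = topology.compare_networks(records)
            _write_table(ranked, outdir / "topology.tsv", config, index=False)
            return records

        do_networks()

    # ---- C-score per group -----------------------------------------------
    @_stage("cscore")
    def do_cscore():
        rows = []
        cs_seeds = s_cscore.spawn(len(pd.unique(groups)))
        for g, gseed in zip(pd.unique(groups), cs_seeds):
            members = list(groups[groups == g].index)
            gtable = _group_table(rarefied.table, members, config.top_k)
            pa = preprocess.to_presence_absence(gtable).T  # OTUs × samples
            res = c_score_null_test(pa, n_null=config.cscore_nulls, seed=gseed)
            rows.append({"group": g, "observed_c": res.observed_c,
                         "null_mean": res.null_mean, "null_sd": res.null_sd,
                         "ses": res.ses, "p_value": res.p_value,
                         "n_null": res.n_null, "degenerate": res.degenerate})
        df = pd.DataFrame(rows)
        _write_table(df, outdir / "cscore.tsv", config, index=False)
        return df

    do_cscore()

    # ---- group statistics -------------------------------------------------
    @_stage("stats")
    def do_stats():
        nri = alpha["alpha_nri"].dropna()
        disp = stats.tukey_letters(nri, groups.loc[nri.index])
        _write_table(disp.table, outdir / "letters.tsv", config)

        cov = metadata.covariates.loc[f_matrix.index].copy()
        cov["richness"] = alpha["richness"]
        cov["alpha_mpd"] = alpha["alpha_mpd"]
        cov["alpha_nri"] = alpha["alpha_nri"]
        for fname, variables in (("panel.tsv", PANEL_VARS),
                                 ("calorimetry_panel.tsv", CALORIMETRY_VARS)):
            use = [v for v in variables if v in cov.columns]
            panel = stats.pearson_panel(cov, use)
            display = panel.r.round(3).astype(str) + panel.stars
            _write_table(display, outdir / fname, config)

        rows = []
        if "yield" in cov.columns:
            for xvar in ("alpha_nri", "alpha_mpd"):
                fit = stats.quadratic_fit(cov[xvar], cov["yield"])
                rows.append({"x": xvar, "y": "yield",
                             "intercept": fit.intercept, "linear": fit.linear,
                             "quadratic": fit.quadratic, "R": fit.r,
                             "R_linear": fit.r_linear, "p_model": fit.p_model,
                             "vertex": fit.vertex})
        _write_table(pd.DataFrame(rows), outdir / "quad.tsv", config,
                     index=False)
        return disp

    do_stats()
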