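"""Configured, logged, resumable analysis pipeline.

Stages: simulate -> cluster -> quantify -> stats -> dynamics -> network ->
varpart -> phylo. Every stage reads/writes plain TSV under the run
directory, all thresholds live in one serialisable config carrying the
standard defaults (98% clustering identity; 100% coverage / 2x depth
retention; seasonal alpha 0.05; persistent/sporadic detection cuts
0.85/0.15; 5x downsampling; LSA delay 3 with p < 0.0015, Q < 0.05,
|rho| >= 0.6 and <5-node subnetwork pruning; forward-selection alpha 0.1;
200 permutations), and a provenance manifest records the config hash and
seed so a rerun with the same config and seed reproduces every output
byte-identically. Completed stages are skipped when their marker matches
the current config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import abundance as ab
from . import community as cs
from . import dynamics as dyn
from . import io as pio
from . import lsa
from . import phylo as ph
from . import varpart as vp
from .clustering import SequenceRecord, clusters_to_table, dereplicate_and_cluster
from .synthetic import SimulationConfig, config_from_dict, simulate_dataset

log = logging.getLogger("phagedyn")

ALL_STAGES = ("simulate", "cluster", "quantify", "stats", "dynamics", "network", "varpart", "phylo")


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    input_dir: str | None = None  # when None, the simulate stage must run
    fasta: str | None = None  # defaults to the simulated markers.fasta
    tree: str | None = None  # newick; a seeded random tree is drawn if absent
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    cluster_threshold: float = 0.98
    seasonal_alpha: float = 0.05
    persistent_min: float = 0.85
    sporadic_max: float = 0.15
    class_precedence: str = "persistent_first"
    downsample_factor: float = 5.0
    k_seasonal: int = 8
    k_trend: int = 10
    lsa_max_delay: int = 3
    lsa_p_max: float = 0.0015
    lsa_q_max: float = 0.05
    lsa_rho_min: float = 0.6
    lsa_min_subnetwork: int = 5
    lsa_p_method: str = "theoretical"
    lsa_n_perm: int = 1000
    network_max_species: int = 100  # per fraction, by mean abundance
    date_window: tuple[str, str] | None = None
    ordistep_alpha: float = 0.1
    n_perm: int = 200

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name, v, lo, hi in (
            ("cluster_threshold", self.cluster_threshold, 0.0, 1.0),
            ("seasonal_alpha", self.seasonal_alpha, 0.0, 1.0),
            ("persistent_min", self.persistent_min, 0.0, 1.0),
            ("sporadic_max", self.sporadic_max, 0.0, 1.0),
            ("lsa_p_max", self.lsa_p_max, 0.0, 1.0),
            ("lsa_q_max", self.lsa_q_max, 0.0, 1.0),
            ("lsa_rho_min", self.lsa_rho_min, 0.0, 1.0),
            ("ordistep_alpha", self.ordistep_alpha, 0.0, 1.0),
        ):
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.downsample_factor <= 0:
            raise ValueError("downsample_factor must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["simulate"]["gene_length_range"] = list(self.simulate.gene_length_range)
        if self.date_window is not None:
            d["date_window"] = list(self.date_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d:
            d["simulate"] = config_from_dict(dict(d["simulate"]))
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if d.get("date_window") is not None:
            d["date_window"] = tuple(d["date_window"])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _marker_path(outdir: str, stage: str) -> str:
    return os.path.join(outdir, f".{stage}.done")


def _stage_done(outdir: str, stage: str, cfg_hash: str) -> bool:
    p = _marker_path(outdir, stage)
    return os.path.exists(p) and open(p).read().strip() == cfg_hash


def _mark_done(outdir: str, stage: str, cfg_hash: str) -> None:
    with open(_marker_path(outdir, stage), "w") as fh:
        fh.write(cfg_hash + "\n")


def _dates(ds) -> pd.PeriodIndex:
    return pd.PeriodIndex(list(ds.counts_viral.samples), freq="M")


def run(config: PipelineConfig, outdir: str) -> dict:
    """Execute the configured stages, returning a dict of stage outputs."""
    os.makedirs(outdir, exist_ok=True)
    cfg_hash = config.config_hash()
    handler = logging.FileHandler(os.path.join(outdir, "pipeline.log"))
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    try:
        config.to_yaml(os.path.join(outdir, "config.yaml"))
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(
                {"config_hash": cfg_hash, "seed": config.seed, "version": __version__},
                fh,
                indent=2,
                sort_keys=True,
            )
        data_dir = os.path.join(outdir, "data")
        log.info("run: seed=%d hash=%s stages=%s", config.seed, cfg_hash, config.stages)

        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            if _stage_done(outdir, stage, cfg_hash):
                log.info("stage %s: outputs current, skipping", stage)
                continue
            log.info("stage %s: running", stage)
            try:
                _STAGE_FUNCS[stage](config, outdir, data_dir, results)
            except Exception as e:  # noqa: BLE001 - halt with stage provenance
                raise StageFailure(stage, e) from e
            _mark_done(outdir, stage, cfg_hash)
        return results
    finally:
        log.removeHandler(handler)
        handler.close()


def _load_data(config: PipelineConfig, data_dir: str):
    src = data_dir if os.path.exists(os.path.join(data_dir, "months.tsv")) else config.input_dir
    if src is None:
        raise FileNotFoundError("no input data: enable the simulate stage or set input_dir")
    return pio.read_dataset(src)


def _stage_simulate(config, outdir, data_dir, results) -> None:
    ds = simulate_dataset(config.simulate, config.seed)
    pio.write_dataset(ds, data_dir)
    results["dataset"] = ds
    log.info(
        "simulate: %d species x %d sampled months", len(ds.truth), len(ds.counts_viral.samples)
    )


def _stage_cluster(config, outdir, data_dir, results) -> None:
    fasta = config.fasta or os.path.join(data_dir, "markers.fasta")
    if not os.path.exists(fasta):
        log.info("cluster: no FASTA at %s, skipping", fasta)
        return
    seqs = pio.read_fasta(fasta)
    records = [SequenceRecord(k, v) for k, v in seqs.items()]
    clusters = dereplicate_and_cluster(records, config.cluster_threshold)
    table = clusters_to_table(clusters, records)
    table.to_csv(os.path.join(outdir, "clusters.tsv"), sep="\t", index=False)
    results["clusters"] = clusters
    log.info("cluster: %d sequences -> %d clusters at %.1f%% identity",
             len(records), len(clusters), 100 * config.cluster_threshold)


def _stage_quantify(config, outdir, data_dir, results) -> None:
    ds = results.get("dataset") or _load_data(config, data_dir)
    results["dataset"] = ds
    for table in (ds.counts_viral, ds.counts_cellular):
        at = ab.abundance_table(table)
        tag = table.fraction_label
        pio.write_matrix(at.rpkm, os.path.join(outdir, f"rpkm_{tag}.tsv"), "species")
        pio.write_matrix(at.rel_abund, os.path.join(outdir, f"rel_abund_{tag}.tsv"), "species")
        results[f"abundance_{tag}"] = at
        log.info("quantify[%s]: retained %d/%d species", tag, len(at.rpkm), len(table.species))


def _stage_stats(config, outdir, data_dir, results) -> None:
    ds = results.get("dataset") or _load_data(config, data_dir)
    rows = []
    for table in (ds.counts_viral, ds.counts_cellular):
        rich = cs.chao_incidence(table.counts.to_numpy() > 0)
        rows.append(
            {
                "fraction": table.fraction_label,
                "s_obs": rich.s_obs,
                "chao": rich.chao,
                "chao_se": rich.chao_se,
                "q1": rich.q1,
                "q2": rich.q2,
                "n_samples": rich.n_samples,
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "richness.tsv"), sep="\t", index=False)

    at = results.get("abundance_viral") or ab.abundance_table(ds.counts_viral)
    dates = _dates(ds)
    lagged = cs.similarity_vs_lag(at.rel_abund, dates)
    lag_df = pd.DataFrame(
        [
            {"lag_months": l.lag_months, "n_pairs": len(l.similarities), "mean": l.mean, "se": l.se}
            for l in lagged.values()
        ]
    )
    lag_df.to_csv(os.path.join(outdir, "lag_similarity.tsv"), sep="\t", index=False)
    fit = cs.fit_lag_sine(lagged)
    pd.DataFrame([dataclasses.asdict(fit)]).to_csv(
        os.path.join(outdir, "lag_sine_fit.tsv"), sep="\t", index=False
    )
    rank = cs.rank_abundance(at.rpkm)
    rank.to_csv(os.path.join(outdir, "rank_abundance.tsv"), sep="\t", index_label="species")
    counts0 = ds.counts_viral.counts.iloc[:, 0].to_numpy().astype(int)
    total = int(counts0.sum())
    depths = np.unique(np.linspace(1, total, 25, dtype=int))
    rare = cs.rarefaction_curve(counts0, depths)
    pd.DataFrame({"depth": depths, "expected_richness": rare}).to_csv(
        os.path.join(outdir, "rarefaction_first_sample.tsv"), sep="\t", index=False
    )
    results["lagged"] = lagged
    results["lag_sine_fit"] = fit
    log.info("stats: sine-fit p=%.3g", fit.p_value)


def _classify_kwargs(config) -> dict:
    return dict(
        thresholds=dyn.ClassThresholds(
            config.seasonal_alpha, config.persistent_min, config.sporadic_max
        ),
        precedence=config.class_precedence,
        k_seasonal=config.k_seasonal,
        k_trend=config.k_trend,
    )


def _stage_dynamics(config, outdir, data_dir, results) -> None:
    ds = results.get("dataset") or _load_data(config, data_dir)
    dates = _dates(ds)
    kw = _classify_kwargs(config)
    for table in (ds.counts_viral, ds.counts_cellular):
        cls = dyn.classify_table(table, dates, **kw)
        cls.to_csv(os.path.join(outdir, f"classification_{table.fraction_label}.tsv"), sep="\t")
        results[f"classification_{table.fraction_label}"] = cls
        log.info("dynamics[%s]: %s", table.fraction_label, dyn.class_counts(cls))
    robust = dyn.downsampling_robustness(
        ds.counts_viral, dates, factor=config.downsample_factor, **kw
    )
    pd.DataFrame(
        [{"factor": config.downsample_factor, "chi2": robust["chi2"],
          "p_value": robust["p_value"], "df": robust["df"]}]
    ).to_csv(os.path.join(outdir, "downsampling_robustness.tsv"), sep="\t", index=False)
    ca = dyn.class_counts(results["classification_viral"])
    cb = dyn.class_counts(results["classification_cellular"])
    stat, p, df = dyn.compare_class_composition(ca, cb)
    pd.DataFrame([{"chi2": stat, "p_value": p, "df": df}]).to_csv(
        os.path.join(outdir, "fraction_class_comparison.tsv"), sep="\t", index=False
    )
    results["downsampling"] = robust


def _series_with_missing(values: pd.DataFrame, ds) -> dict[str, np.ndarray]:
    """Expand sampled-month columns onto the full month axis with NaN gaps."""
    full = [str(m) for m in ds.months]
    out = {}
    expanded = values.reindex(columns=full)
    for name, row in expanded.iterrows():
        out[name] = row.to_numpy(dtype=float)
    return out


def _stage_network(config, outdir, data_dir, results) -> None:
    ds = results.get("dataset") or _load_data(config, data_dir)
    series: dict[str, tuple[str, np.ndarray]] = {}
    for tag, key in (("viral", "virus_viral_fraction"), ("cellular", "virus_cellular_fraction")):
        at = results.get(f"abundance_{tag}") or ab.abundance_table(
            ds.counts_viral if tag == "viral" else ds.counts_cellular
        )
        top = at.rpkm.mean(axis=1).nlargest(config.network_max_species).index
        for name, arr in _series_with_missing(at.rpkm.loc[top], ds).items():
            series[f"{name}|{tag}"] = (key, arr)
    for name, arr in _series_with_missing(ds.host_abundance, ds).items():
        role = "host_ecotype" if name.startswith("eco") else "host_asv"
        series[name] = (role, arr)
    for name, arr in _series_with_missing(ds.env, ds).items():
        series[name] = ("environment", arr)
    if config.date_window is not None:
        lo, hi = pd.Period(config.date_window[0], "M"), pd.Period(config.date_window[1], "M")
        sel = np.array([(lo <= m <= hi) for m in ds.months])
        series = {k: (role, arr[sel]) for k, (role, arr) in series.items()}
    net = lsa.build_network(
        series,
        max_delay=config.lsa_max_delay,
        filters=lsa.LSAFilters(config.lsa_p_max, config.lsa_q_max, config.lsa_rho_min),
        min_subnetwork=config.lsa_min_subnetwork,
        p_method=config.lsa_p_method,
        n_perm=config.lsa_n_perm,
        seed=config.seed,
    )
    net.edges.to_csv(os.path.join(outdir, "network_edges.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(net.tally.items()), columns=["category", "n_edges"]
    ).to_csv(os.path.join(outdir, "network_tally.tsv"), sep="\t", index=False)
    lsa.write_graphml(net, os.path.join(outdir, "network.graphml"))
    results["network"] = net
    log.info("network: %d nodes, %d edges after filtering", net.graph.number_of_nodes(),
             net.graph.number_of_edges())


def _stage_varpart(config, outdir, data_dir, results) -> None:
    ds = results.get("dataset") or _load_data(config, data_dir)
    at = results.get("abundance_viral") or ab.abundance_table(ds.counts_viral)
    host = ds.host_abundance.T  # samples x taxa
    Y = vp.hellinger_transform(host)
    viral = vp.hellinger_transform(at.rel_abund.T + 1e-12)
    env = vp.standardize(ds.env.T)
    rows = []
    for level, cols in (
        ("all_asv", [c for c in host.columns if not c.startswith("eco")]),
        ("ecotype", [c for c in host.columns if c.startswith("eco")]),
    ):
        if len(cols) < 2:
            continue
        Yl = Y[cols].to_numpy()
        ax1 = vp.principal_axes(viral.to_numpy())
        ax2 = vp.principal_axes(env)
        sel1 = vp.forward_select_axes(Yl, ax1, config.ordistep_alpha, config.n_perm, config.seed)
        sel2 = vp.forward_select_axes(Yl, ax2, config.ordistep_alpha, config.n_perm, config.seed)
        X1 = ax1[:, sel1] if sel1 else ax1[:, :1]
        X2 = ax2[:, sel2] if sel2 else ax2[:, :1]
        part = vp.variance_partition(Yl, X1, X2, n_perm=config.n_perm, seed=config.seed)
        rows.append(
            {
                "response_level": level,
                "n_axes_viral": X1.shape[1],
                "n_axes_env": X2.shape[1],
                "unique_viral": part.unique_x1,
                "unique_env": part.unique_x2,
                "shared": part.shared,
                "unexplained": part.unexplained,
                "p_unique_viral": part.p_unique_x1,
                "p_unique_env": part.p_unique_x2,
            }
        )
        results[f"varpart_{level}"] = part
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "varpart.tsv"), sep="\t", index=False)
    log.info("varpart: %d response levels", len(rows))


def _random_labeled_tree(taxa: list[str], seed: int) -> dendropy.Tree:
    """Seeded random bifurcating topology over the given taxa (synthetic)."""
    rng = random.Random(seed)
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=ns, num_extant_tips=len(taxa), rng=rng
    )
    return tree


def _stage_phylo(config, outdir, data_dir, results) -> None:
    ds = results.get("dataset") or _load_data(config, data_dir)
    cls = results.get("classification_viral")
    if cls is None:
        p = os.path.join(outdir, "classification_viral.tsv")
        if not os.path.exists(p):
            log.info("phylo: no classification available, skipping")
            return
        cls = pd.read_csv(p, sep="\t", index_col="species")
    traits = cls["class"].to_dict()
    if config.tree:
        tree = ph.read_tree(config.tree)
    else:
        tree = _random_labeled_tree(sorted(traits), config.seed)
        tree.write(path=os.path.join(outdir, "synthetic_tree.nwk"), schema="newick")
    report = ph.monophyly_fraction(tree, traits, n_perm=199, seed=config.seed)
    ph.report_table(report).to_csv(os.path.join(outdir, "phylo_traits.tsv"), sep="\t", index=False)
    results["phylo"] = report
    log.info("phylo: %d observed transitions (null mean %.1f)", report.observed_transitions,
             report.null_transitions.mean())


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cluster": _stage_cluster,
    "quantify": _stage_quantify,
    "stats": _stage_stats,
    "dynamics": _stage_dynamics,
    "network": _stage_network,
    "varpart": _stage_varpart,
    "phylo": _stage_phylo,
}
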