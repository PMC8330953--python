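"""End-to-end pipeline: QC -> ecology -> trends -> correlations ->
stability -> cores, from either real OTU tables or a synthetic cohort.

Every stage writes TSV artifacts to the run directory plus a manifest
recording stage parameters, the global seed and the SHA-256 of each
output file, so a rerun with the same inputs and seed is byte-identical
and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    amplicon_qc as qc,
    core_community as core,
    correlation_screen as cs,
    ecology_stats as eco,
    stability_bootstrap as sb,
    synthetic_cohort as sc,
    trend_bayes as tb,
)

__all__ = ["RunConfig", "texture_trends", "run_pipeline", "STAGES"]

log = logging.getLogger("pitfoam")

STAGES = ("qc", "ecology", "trends", "correlations", "stability", "cores")

_FLOAT_FMT = "%.10g"

DEFAULT_TREND_VARIABLES = list(sc.DIET_VARIABLES) + list(sc.MANURE_VARIABLES)
DEFAULT_CORRELATION_VARIABLES = [
    "LCFA",
    "SCFA",
    "acetic_acid",
    "pH",
    "organic_N",
    "temperature",
    "MPR",
]


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of real input paths or a
    synthetic cohort config must be present."""

    outdir: str = "pitfoam_run"
    seed: int = 0
    # real inputs
    counts_16s: str | None = None
    taxonomy_16s: str | None = None
    counts_mcra: str | None = None
    taxonomy_mcra: str | None = None
    metadata: str | None = None
    # or a synthetic cohort
    synthetic: sc.CohortConfig | None = None
    # stage parameters
    min_otu_total: int = 5
    n_perm: int = 999
    n_perm_farm: int = 199
    run_nmds: bool = True
    nmds_k: int = 2
    nmds_restarts: int = 2
    nmds_max_iter: int = 200
    trend_variables: list = field(default_factory=lambda: list(DEFAULT_TREND_VARIABLES))
    correlation_variables: list = field(
        default_factory=lambda: list(DEFAULT_CORRELATION_VARIABLES)
    )
    alpha: float = 0.05
    top_k: int = 5
    hoeffding_perm: int = 199
    bf_threshold: float = 3.0
    n_boot: int = 999
    prevalence: float = 1.0
    log_level: str = "INFO"

    def validate(self) -> None:
        real = all(
            getattr(self, f) is not None for f in ("counts_16s", "counts_mcra", "metadata")
        )
        some_real = any(
            getattr(self, f) is not None for f in ("counts_16s", "counts_mcra", "metadata")
        )
        if self.synthetic is not None and some_real:
            raise ValueError("give either real input paths or a synthetic config, not both")
        if self.synthetic is None and not real:
            raise ValueError(
                "need counts_16s, counts_mcra and metadata paths, or a synthetic config"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        config = cls(**raw)
        if synth is not None:
            if isinstance(synth, dict):
                if "texture_transition" in synth:
                    synth["texture_transition"] = np.asarray(synth["texture_transition"])
                if "diet_means" in synth:
                    synth["diet_means"] = {
                        (v, t): m for v, t, m in synth["diet_means"]
                    }
                if "planted_correlations" in synth:
                    synth["planted_correlations"] = [
                        tuple(p) for p in synth["planted_correlations"]
                    ]
                config.synthetic = sc.CohortConfig(**synth)
            else:
                config.synthetic = synth
        return config


def texture_trends(metadata: pd.DataFrame, group_col: str = "texture", month_col: str = "month"):
    """Per-month texture proportions and their linear trend slopes.

    Returns a (months x textures) proportion table whose rows sum to 1
    (months with zero samples are excluded) and a dict of ordinary
    least-squares slopes of proportion versus month index per texture.
    """
    months = sorted(metadata[month_col].unique())
    if len(months) < 2:
        raise ValueError("need at least 2 months")
    counts = (
        metadata.groupby([month_col, group_col]).size().unstack(fill_value=0)
    )
    counts = counts.loc[counts.sum(axis=1) > 0]
    props = counts.div(counts.sum(axis=1), axis=0)
    slopes = {
        str(tex): float(np.polyfit(props.index.to_numpy(dtype=float), props[tex].to_numpy(), 1)[0])
        for tex in props.columns
    }
    return props, slopes


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, seed: int):
        self.outdir = outdir
        self.record = {"seed": seed, "stages": {}}

    def add(self, stage: str, params: dict, outputs: list[Path]):
        self.record["stages"][stage] = {
            "params": params,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    def write(self):
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.record, fh, indent=1, sort_keys=True)


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    return path


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        t16, tmc, meta, truth = sc.generate_cohort(synth)
        return t16, tmc, meta, truth
    t16 = qc.OtuTable.from_tsv(config.counts_16s, config.taxonomy_16s)
    tmc = qc.OtuTable.from_tsv(config.counts_mcra, config.taxonomy_mcra)
    meta = pd.read_csv(config.metadata, sep="\t", index_col=0)
    return t16, tmc, meta, None


def run_pipeline(config: RunConfig, stages=None) -> Path:
    """Execute the requested stages in order; returns the run directory.

    The pipeline is a pure function of (inputs, config, seed): rerunning
    with the same arguments reproduces every output file byte for byte.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config.seed)

    table_16s, table_mcra, metadata, _truth = _load_inputs(config)
    meta_path = _write(metadata, outdir / "metadata.tsv")
    manifest.add("inputs", {"synthetic": config.synthetic is not None}, [meta_path])

    missing = [
        c
        for c in ("farm", "month", "texture")
        if c not in metadata.columns
    ]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")

    filtered: dict[str, qc.OtuTable] = {}
    relabund: dict[str, pd.DataFrame] = {}
    for marker, table in (("16s", table_16s), ("mcra", table_mcra)):
        min_reads, min_cov = qc.SAMPLE_FILTER_PRESETS[marker]
        t1, rep_otus = qc.filter_rare_otus(table, config.min_otu_total)
        t2, rep_samples = qc.filter_samples(t1, min_reads, min_cov)
        log.info(
            "%s QC: %d/%d OTUs, %d/%d samples retained",
            marker, t2.n_otus, table.n_otus, t2.n_samples, table.n_samples,
        )
        filtered[marker] = t2
        relabund[marker] = qc.relative_abundance(t2)
        rep_otus.to_json(outdir / f"qc_otus_{marker}.json")
        rep_samples.to_json(outdir / f"qc_samples_{marker}.json")
    if "qc" in stages:
        outputs = []
        for marker in ("16s", "mcra"):
            outputs.append(
                _write(filtered[marker].counts, outdir / f"filtered_{marker}.tsv")
            )
        manifest.add(
            "qc",
            {"min_otu_total": config.min_otu_total, "presets": qc.SAMPLE_FILTER_PRESETS},
            outputs,
        )

    meta_by_marker = {
        m: metadata.loc[[s for s in filtered[m].sample_ids if s in metadata.index]]
        for m in ("16s", "mcra")
    }

    if "ecology" in stages:
        rows, outputs = [], []
        for marker in ("16s", "mcra"):
            meta_m = meta_by_marker[marker]
            dm = eco.bray_curtis(relabund[marker].loc[:, meta_m.index])
            res_farm = eco.permanova(
                dm, meta_m["farm"], n_perm=config.n_perm_farm,
                seed=config.seed, grouping_name=f"farm[{marker}]",
            )
            res_tex = eco.permanova(
                dm, meta_m["texture"], n_perm=config.n_perm,
                strata=meta_m["farm"], seed=config.seed,
                grouping_name=f"texture[{marker}]", strata_name="farm",
            )
            rows += [res_farm.as_row(), res_tex.as_row()]
            if config.run_nmds:
                ordn = eco.nmds(
                    dm, k=config.nmds_k, n_restarts=config.nmds_restarts,
                    max_iter=config.nmds_max_iter, seed=config.seed,
                )
                coords = pd.DataFrame(
                    ordn.coordinates,
                    index=ordn.sample_ids,
                    columns=[f"NMDS{i + 1}" for i in range(config.nmds_k)],
                )
                coords["stress"] = ordn.stress
                outputs.append(_write(coords, outdir / f"nmds_{marker}.tsv"))
                if "MPR" in meta_m.columns:
                    surf = eco.fit_env_surface(
                        ordn, meta_m["MPR"].to_numpy(dtype=float), variable="MPR"
                    )
                    rows.append(
                        {"factor": f"MPR_surface[{marker}]", "R2": surf.R2,
                         "p_value": float("nan"), "pseudo_F": float("nan"),
                         "strata": "", "n_permutations": 0}
                    )
        perm_path = _write(
            pd.DataFrame(rows).set_index("factor"), outdir / "permanova.tsv"
        )
        manifest.add(
            "ecology",
            {"n_perm": config.n_perm, "n_perm_farm": config.n_perm_farm,
             "nmds": config.run_nmds},
            outputs + [perm_path],
        )

    if "trends" in stages:
        meta16 = meta_by_marker["16s"]
        variables = [v for v in config.trend_variables if v in metadata.columns]
        results = tb.trend_table(
            meta16, variables, bf_threshold=config.bf_threshold, seed=config.seed
        )
        props, slopes = texture_trends(metadata)
        out1 = _write(
            tb.trend_results_to_frame(results).set_index("variable"),
            outdir / "trend_table.tsv",
        )
        trend_frame = props.copy()
        trend_frame.loc["slope"] = [slopes[str(c)] for c in props.columns]
        out2 = _write(trend_frame, outdir / "texture_trends.tsv")
        manifest.add("trends", {"bf_threshold": config.bf_threshold}, [out1, out2])

    if "correlations" in stages:
        meta16 = meta_by_marker["16s"]
        variables = [v for v in config.correlation_variables if v in metadata.columns]
        pairs = list(combinations(variables, 2))
        records = cs.screen(
            meta16[variables], meta16["texture"], pairs,
            alpha=config.alpha, top_k=config.top_k,
            n_perm=config.hoeffding_perm, seed=config.seed,
        )
        out = _write(
            cs.records_to_frame(records).set_index(["group", "var_a", "var_b"]),
            outdir / "correlations.tsv",
        )
        edges = cs.records_to_frame(
            [r for r in records if r.classification in ("monotonic", "non-monotonic")]
        )
        if len(edges):
            edges = edges[["var_a", "var_b", "sign", "strength", "group"]]
        out_edges = _write(edges.set_index("var_a") if len(edges) else edges,
                           outdir / "correlation_edges.tsv")
        manifest.add(
            "correlations",
            {"alpha": config.alpha, "n_perm": config.hoeffding_perm},
            [out, out_edges],
        )

    if "stability" in stages:
        meta16 = meta_by_marker["16s"]
        fits = []
        for tex in sc.TEXTURES:
            if (meta16["texture"] == tex).sum() < 10:
                log.warning("skipping stability for %s: too few samples", tex)
                continue
            try:
                fits.append(
                    sb.bootstrap_slopes(
                        relabund["16s"].loc[:, meta16.index], meta16, tex,
                        n_boot=config.n_boot, seed=config.seed,
                    )
                )
            except (RuntimeError, ValueError) as err:
                log.warning("stability fit for %s failed: %s", tex, err)
        rows = [
            {
                "group": f.group, "pairs_used": f.pairs_used, "a_hat": f.a_hat,
                "b_hat": f.b_hat, "n_boot": f.n_boot,
                "slope_q025": float(np.quantile(f.bootstrap_slopes, 0.025)),
                "slope_median": float(np.median(f.bootstrap_slopes)),
                "slope_q975": float(np.quantile(f.bootstrap_slopes, 0.975)),
                "failed_replicates": f.n_failed_replicates,
            }
            for f in fits
        ]
        stab_cols = [
            "group", "pairs_used", "a_hat", "b_hat", "n_boot", "slope_q025",
            "slope_median", "slope_q975", "failed_replicates",
        ]
        out1 = _write(
            pd.DataFrame(rows, columns=stab_cols).set_index("group"),
            outdir / "stability.tsv",
        )
        ovl_rows = [
            {"group_a": o.group_a, "group_b": o.group_b, "ovl": o.ovl}
            for o in sb.pairwise_overlap(fits)
        ]
        # pooled comparison: no-foam against crust+foam combined
        by_group = {f.group: f for f in fits}
        if "no-foam" in by_group and len(by_group) == 3:
            pooled = np.concatenate(
                [by_group["crust"].bootstrap_slopes, by_group["foam"].bootstrap_slopes]
            )
            ovl_rows.append(
                {"group_a": "no-foam", "group_b": "crust+foam",
                 "ovl": sb.overlap_coefficient(
                     by_group["no-foam"].bootstrap_slopes, pooled)}
            )
        out2 = _write(
            pd.DataFrame(ovl_rows, columns=["group_a", "group_b", "ovl"]).set_index(
                "group_a"
            ),
            outdir / "overlap.tsv",
        )
        slope_frame = pd.DataFrame(
            {f.group: f.bootstrap_slopes for f in fits}
        )
        out3 = _write(slope_frame, outdir / "bootstrap_slopes.tsv")
        manifest.add("stability", {"n_boot": config.n_boot}, [out1, out2, out3])

    if "cores" in stages:
        outputs = []
        for marker, rank in (("16s", "genus"), ("mcra", "species")):
            table = filtered[marker]
            meta_m = meta_by_marker[marker]
            cores = [
                core.core_taxa(table, meta_m, tex, prevalence=config.prevalence)
                for tex in sc.TEXTURES
                if (meta_m["texture"] == tex).sum() > 0
            ]
            if len(cores) >= 2:
                venn = core.venn_partition(cores)
                outputs.append(
                    _write(
                        pd.DataFrame(
                            sorted(venn.items()), columns=["region", "count"]
                        ).set_index("region"),
                        outdir / f"venn_{marker}.tsv",
                    )
                )
            agg = qc.aggregate_taxonomy(table, rank)
            rel = qc.relative_abundance(agg)
            records = core.differential_abundance(
                rel, meta_m, rank=rank, n_boot=min(config.n_boot, 499),
                seed=config.seed,
            )
            outputs.append(
                _write(
                    core.diff_abundance_to_frame(records).set_index("taxon"),
                    outdir / f"diff_abundance_{marker}_{rank}.tsv",
                )
            )
        manifest.add("cores", {"prevalence": config.prevalence}, outputs)

    manifest.write()
    return outdir
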