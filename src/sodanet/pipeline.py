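"""End-to-end per-lake analysis pipeline.

Ingest (or simulate) → rarefy → core partition → turnover / distance decay /
PERMANOVA → network filter → local similarity associations → synchronous and
time-shifted networks → keystones → TSV/GraphML reports, all driven by a
single validated configuration and a master seed.  Per-stage randomness is
derived from the master seed through ``numpy.random.SeedSequence`` so a rerun
with the same configuration reproduces every output byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import partition_core, core_contribution
from .dynamics import bc_matrix, distance_decay, decay_frame, permanova, turnover_series
from .keystones import (
    annotate_and_export,
    build_network,
    edge_list_frame,
    keystone_report,
    network_properties,
)
from .lsa import pairwise_associations, prepare_timeseries, significant_edges
from .synthetic import generate_study, write_truth
from .tables import (
    DEFAULT_SEASON_PARTITION,
    OtuTable,
    filter_for_network,
    rarefy,
    read_otu_table,
    write_otu_table,
)

log = logging.getLogger("sodanet")


@dataclass
class PipelineConfig:
    """Validated pipeline settings.

    Either ``inputs`` (lake -> count TSV path, plus ``metadata_path``) or
    ``synthetic`` (keyword arguments for
    :func:`sodanet.synthetic.generate_study`) must be provided.
    """

    outdir: str = "sodanet_out"
    seed: int = 0
    inputs: dict | None = None
    metadata_path: str | None = None
    synthetic: dict | None = None
    depth_policy: str = "min"  # "min" or "fixed"
    depth: int | None = None
    abun_threshold: float = 0.01
    read_threshold: int = 10
    sample_min: int = 3
    delay_limit: int = 1
    alpha: float = 0.01
    n_perm: int = 10000
    q_method: str = "fdr_bh"
    fill: str = "linear"
    wi_steps: int = 3
    keystone_strict: float = 1.0
    keystone_min_count: int = 6
    season_partition: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SEASON_PARTITION.items()}
    )
    lakes: list | None = None  # restrict to a subset

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load YAML or JSON config; keyword overrides win."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def validate_config(config: PipelineConfig) -> list:
    """Return a list of violations (empty means the config is valid)."""
    bad = []
    if config.inputs is None and config.synthetic is None:
        bad.append("inputs/synthetic: one input source is required")
    if config.inputs is not None and config.metadata_path is None:
        bad.append("metadata_path: required with file inputs")
    if config.depth_policy not in ("min", "fixed"):
        bad.append(f"depth_policy: unknown policy {config.depth_policy!r}")
    if config.depth_policy == "fixed" and (config.depth is None or config.depth <= 0):
        bad.append("depth: fixed policy requires a positive depth")
    for name in ("abun_threshold", "alpha"):
        v = getattr(config, name)
        if not 0 < v < 1:
            bad.append(f"{name}: must be in (0, 1)")
    for name in ("read_threshold", "sample_min", "delay_limit", "n_perm", "wi_steps"):
        if getattr(config, name) < 1:
            bad.append(f"{name}: must be positive")
    if config.fill not in ("none", "zero", "linear", "nearest"):
        bad.append(f"fill: unknown method {config.fill!r}")
    # season partition must cover 1..T disjointly
    spans = sorted((lo, hi, s) for s, (lo, hi) in config.season_partition.items())
    for (lo, hi, s) in spans:
        if hi < lo:
            bad.append(f"season_partition.{s}: empty span")
    for (_, hi1, s1), (lo2, _, s2) in zip(spans, spans[1:]):
        if lo2 <= hi1:
            bad.append(f"season_partition: {s1} and {s2} overlap")
        elif lo2 > hi1 + 1:
            bad.append(f"season_partition: gap between {s1} and {s2}")
    return bad


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        params = dict(config.synthetic)
        params.setdefault("seed", config.seed)
        study = generate_study(**params)
        return study.tables, study.metadata, study.truth
    tables = {}
    meta = None
    for lake, path in config.inputs.items():
        table, meta = read_otu_table(path, config.metadata_path)
        sub = meta.table.loc[
            (meta.table["lake"] == lake) & (~meta.table["missing"])
        ].index
        tables[lake] = table.select_samples([s for s in sub if s in table.data.index])
    return tables, meta, None


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    A failure in one lake's network stage is recorded in the manifest and
    does not abort the other lakes.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    status: dict[str, str] = {}
    try:
        tables, metadata, truth = _load_inputs(config)
        lakes = config.lakes or list(tables)
        log.info("loaded %d lakes: %s", len(lakes), lakes)
        if truth is not None:
            write_truth(truth, outdir / "planted_edges.tsv", outdir / "truth.json")

        # --- rarefaction to a common depth --------------------------------
        if config.depth_policy == "fixed":
            depth = config.depth
        else:
            depth = int(min(int(tables[lk].row_sums().min()) for lk in lakes))
        rarefied: dict[str, OtuTable] = {}
        for k, lake in enumerate(lakes):
            seed_k = int(np.random.SeedSequence([config.seed, 1, k]).generate_state(1)[0] % (2**31))
            rarefied[lake] = rarefy(tables[lake], depth=depth, seed=seed_k)
            write_otu_table(rarefied[lake], outdir / f"{lake}_rarefied.tsv")
        log.info("rarefied to depth %d", depth)

        # --- core partition -----------------------------------------------
        if len(lakes) >= 2:
            part = partition_core(rarefied, lakes)
            part.to_frame().to_csv(outdir / "core_partition.tsv", sep="\t", index=False)
            contrib_rows = []
            for lake in lakes:
                per_sample, pooled = core_contribution(rarefied[lake], part.core)
                for sid, v in per_sample.items():
                    contrib_rows.append({"lake": lake, "sample_id": sid, "core_share": v})
                log.info("%s pooled core share %.3f", lake, pooled)
            pd.DataFrame(contrib_rows).to_csv(
                outdir / "core_contribution.tsv", sep="\t", index=False
            )
        else:
            part = None

        # --- dissimilarity dynamics ---------------------------------------
        turnover_rows, decay_rows = [], []
        for lake in lakes:
            meta_lake = metadata.for_lake(lake).present()
            order = [s for s in meta_lake.index if s in rarefied[lake].data.index]
            times = list(meta_lake.loc[order, "time_index"])
            tab = rarefied[lake].select_samples(order)
            tser = turnover_series(tab, times)
            tser.insert(0, "lake", lake)
            turnover_rows.append(tser)
            dd = decay_frame(distance_decay(tab, times))
            dd.insert(0, "lake", lake)
            decay_rows.append(dd)
        pd.concat(turnover_rows).to_csv(outdir / "turnover.tsv", sep="\t", index=False)
        pd.concat(decay_rows).to_csv(outdir / "distance_decay.tsv", sep="\t", index=False)

        # --- pooled PERMANOVA (lake, then season) -------------------------
        if len(lakes) >= 2:
            all_ids, all_lakes, all_seasons = [], [], []
            mats = []
            common = sorted(set.intersection(*(set(rarefied[lk].otu_ids) for lk in lakes)))
            for lake in lakes:
                meta_lake = metadata.for_lake(lake).present()
                order = [s for s in meta_lake.index if s in rarefied[lake].data.index]
                mats.append(rarefied[lake].select_samples(order).data[common])
                all_ids.extend(order)
                all_lakes.extend([lake] * len(order))
                all_seasons.extend(meta_lake.loc[order, "season"])
            pooled = OtuTable(pd.concat(mats), unit="counts")
            d = bc_matrix(pooled)
            seed_p = int(
                np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % (2**31)
            )
            res = permanova(
                d,
                {"lake": all_lakes, "season": all_seasons},
                n_perm=min(config.n_perm, 999),
                seed=seed_p,
            )
            res.to_frame().to_csv(outdir / "permanova.tsv", sep="\t", index=False)

        # --- associations, networks, keystones per lake -------------------
        for k, lake in enumerate(lakes):
            try:
                _lake_networks(config, outdir, lake, k, rarefied[lake], metadata, part)
                status[lake] = "ok"
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                log.exception("lake %s failed", lake)
                status[lake] = f"failed: {exc}"

        manifest = {
            "config": asdict(config),
            "version": __version__,
            "depth": depth,
            "lakes": lakes,
            "status": status,
        }
        with open(outdir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True, default=str)
    finally:
        log.removeHandler(fh)
        fh.close()
    return outdir


def _lake_networks(config, outdir, lake, lake_idx, table, metadata, part):
    meta_lake = metadata.for_lake(lake).present()
    order = [s for s in meta_lake.index if s in table.data.index]
    times = list(meta_lake.loc[order, "time_index"])
    all_times = list(metadata.for_lake(lake).table["time_index"])
    tab = table.select_samples(order)
    filtered = filter_for_network(
        tab,
        abun_threshold=config.abun_threshold,
        read_threshold=config.read_threshold,
        sample_min=config.sample_min,
    )
    log.info("%s: %d OTUs pass the network filter", lake, len(filtered.otu_ids))
    ts = prepare_timeseries(filtered, times, full_times=all_times, fill=config.fill)
    seed_l = int(
        np.random.SeedSequence([config.seed, 3, lake_idx]).generate_state(1)[0] % (2**31)
    )
    assoc = pairwise_associations(
        ts,
        D=config.delay_limit,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=seed_l,
    )
    assoc.to_csv(outdir / f"{lake}_associations.tsv", sep="\t", index=False)
    sig = significant_edges(assoc)
    sig.to_csv(outdir / f"{lake}_edges.tsv", sep="\t", index=False)

    core = part.core if part is not None else set()
    season_labels = list(meta_lake.loc[order, "season"])
    networks = {}
    props = []
    for which in ("synchronous", "time_shifted"):
        g = build_network(sig, which)
        networks[which] = g
        summary = network_properties(g)
        summary["network"] = which
        props.append(summary)
        annotate_and_export(g, outdir / f"{lake}_{which}.graphml", core=core)
        edge_list_frame(g).to_csv(
            outdir / f"{lake}_{which}_edges.tsv", sep="\t", index=False
        )
    pd.DataFrame(props).to_csv(
        outdir / f"{lake}_network_properties.tsv", sep="\t", index=False
    )
    report = keystone_report(networks, tab, season_labels, core)
    report.to_csv(outdir / f"{lake}_keystones.tsv", sep="\t", index=False)
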