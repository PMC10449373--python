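"""Synthetic multi-lake plankton study generator with known ground truth.

The generator emulates the sampling design of a fortnightly multi-lake
time-series study: several nearby shallow lakes sampled over one productive
season cycle (spring/summer/autumn), with a shared core community plus
lake-specific taxa, unimodal seasonal abundance trajectories, optional
desiccation events that remove sampling dates and replace part of the
community upon refill, and multinomial read sampling at a fixed depth.

Each OTU follows a latent log-abundance trajectory

    latent_k(t) = baseline_k + amplitude_k * exp(-(t - peak_k)^2 / (2 width_k^2)) + eps

with Gaussian observation noise ``eps ~ N(0, sigma^2)``.  For a planted
association (a, b, sign, delay, rho) the anomaly series of ``b`` is replaced
by ``rho * sign * z_a(t - delay) + sqrt(1 - rho^2) * eps'(t)`` where ``z_a``
is the standardized latent of ``a`` and ``eps'`` is a fresh draw of the same
observation-noise process (``N(0, sigma^2)``): ``rho`` weights signal
against one unit of the generator's noise, so at the default ``sigma`` a
strong coupling survives to the observed counts.  The coupling is imposed on
the latent (pre-sampling) series so that failures to recover a planted edge
downstream are attributable to sampling noise rather than to generator
artifacts.  Read counts are then multinomial draws at the given
depth from the softmax of the latent series.

The returned :class:`SyntheticTruth` records the planted core membership,
edges and desiccation schedule and is the recovery target for every
downstream test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import (
    DEFAULT_SEASON_PARTITION,
    OtuTable,
    SampleMetadata,
    season_of,
)

#: Default desiccation schedule: two of five lakes dry out during late
#: summer and autumn, mirroring a study design in which two lakes lost
#: sampling dates to drought.
DEFAULT_DESICCATION: dict[str, tuple[frozenset, float]] = {
    "L4": (frozenset({7, 8, 10, 11, 13}), 0.5),
    "L5": (frozenset({11, 13}), 0.5),
}


@dataclass(frozen=True)
class PlantedEdge:
    """A ground-truth pairwise coupling.

    ``delay`` is the number of sampling intervals by which ``otu_b`` trails
    ``otu_a``: with ``delay=+1`` the series of ``b`` at time ``t`` tracks
    ``a`` at time ``t-1``.  ``sign`` is ``+1`` or ``-1``; ``rho`` in (0, 1]
    is the latent coupling strength.
    """

    otu_a: str
    otu_b: str
    sign: int
    delay: int
    rho: float

    def canonical(self) -> "PlantedEdge":
        """Order members lexicographically, flipping the delay to match."""
        if self.otu_a <= self.otu_b:
            return self
        return PlantedEdge(self.otu_b, self.otu_a, self.sign, -self.delay, self.rho)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study."""

    core_otus: set
    noncore_map: dict
    planted_edges: list
    seasonal_profiles: dict
    desiccation: dict
    seed: int

    def manifest(self) -> dict:
        return {
            "core_otus": sorted(self.core_otus),
            "noncore_map": {k: sorted(v) for k, v in self.noncore_map.items()},
            "planted_edges": [asdict(e) for e in self.planted_edges],
            "desiccation": {
                lake: {"missing": sorted(miss), "phi": phi}
                for lake, (miss, phi) in self.desiccation.items()
            },
            "seed": self.seed,
        }


@dataclass
class SyntheticStudy:
    """Bundle returned by :func:`generate_study`."""

    tables: dict  # lake -> OtuTable (counts)
    metadata: SampleMetadata
    truth: SyntheticTruth
    params: dict = field(default_factory=dict)
    latents: dict = field(default_factory=dict)  # lake -> (otu_ids, n_otus x T latent matrix)

    def lake_table(self, lake: str) -> OtuTable:
        return self.tables[lake]


def _seasonal_latent(rng, n_otus, n_times, sigma):
    """Independent latent trajectories: baseline + Gaussian seasonal bump + noise."""
    t = np.arange(1, n_times + 1, dtype=float)
    baseline = rng.normal(0.0, 0.5, size=n_otus)
    amplitude = rng.uniform(1.0, 2.0, size=n_otus)
    peak = rng.uniform(1.0, n_times, size=n_otus)
    width = rng.uniform(2.0, 4.0, size=n_otus)
    bump = amplitude[:, None] * np.exp(
        -((t[None, :] - peak[:, None]) ** 2) / (2.0 * width[:, None] ** 2)
    )
    noise = rng.normal(0.0, sigma, size=(n_otus, n_times))
    latent = baseline[:, None] + bump + noise
    profiles = {"peak": peak, "width": width, "amplitude": amplitude}
    return latent, profiles


def _standardize(series):
    s = np.asarray(series, dtype=float)
    sd = s.std()
    if sd == 0:
        return np.zeros_like(s)
    return (s - s.mean()) / sd


def generate_study(
    n_lakes: int = 5,
    n_times: int = 14,
    n_core: int = 30,
    n_noncore_per_lake: int = 10,
    depth: int = 5000,
    seed: int = 0,
    planted_edges=None,
    desiccation=None,
    sigma: float = 0.3,
    coupling_scale: float = 1.2,
    delay_limit: int = 1,
    season_partition=None,
    overdispersion: float | None = None,
) -> SyntheticStudy:
    """Generate a multi-lake OTU time series with known ground truth.

    Parameters
    ----------
    n_lakes, n_times:
        Study design; defaults mirror a five-lake, fourteen-occasion
        fortnightly campaign over three seasons.
    n_core, n_noncore_per_lake:
        Number of OTUs shared by all lakes versus private to each lake.
    depth:
        Reads per sample (multinomial sampling depth), minimum 100.
    planted_edges:
        Iterable of ``PlantedEdge`` or ``(otu_a, otu_b, sign, delay, rho)``
        tuples naming core OTUs; planted in every lake.
    desiccation:
        ``lake -> (missing time indices, phi)``; ``phi`` in [0, 1] is the
        fraction of community mass replaced by that lake's private OTUs from
        the refill date onward.  Defaults to two drying lakes when the design
        has five lakes and fourteen times; otherwise no desiccation.
    sigma:
        Latent observation noise standard deviation.
    coupling_scale:
        Amplitude given to the standardized coupled anomaly of a planted
        edge's target OTU (log-abundance units).
    overdispersion:
        Optional Dirichlet concentration; ``None`` gives pure multinomial
        sampling.

    Returns
    -------
    SyntheticStudy
        Per-lake count tables, joint metadata (dry dates flagged missing,
        with no count rows), and the ground truth.
    """
    if n_times < 4:
        raise ValueError("n_times must be at least 4")
    if depth < 100:
        raise ValueError("depth must be at least 100")
    season_partition = season_partition or (
        DEFAULT_SEASON_PARTITION if n_times == 14 else _even_partition(n_times)
    )
    lakes = [f"L{i + 1}" for i in range(n_lakes)]
    if desiccation is None:
        desiccation = (
            {k: v for k, v in DEFAULT_DESICCATION.items() if k in lakes}
            if (n_lakes == 5 and n_times == 14)
            else {}
        )
    desiccation = {
        lake: (frozenset(int(t) for t in miss), float(phi))
        for lake, (miss, phi) in desiccation.items()
    }
    for lake, (miss, phi) in desiccation.items():
        if lake not in lakes:
            raise ValueError(f"desiccation names unknown lake {lake!r}")
        if not 0.0 <= phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")
        if miss - set(range(1, n_times + 1)):
            raise ValueError("missing time indices outside 1..n_times")

    edges = []
    for e in planted_edges or []:
        e = e if isinstance(e, PlantedEdge) else PlantedEdge(*e)
        if abs(e.delay) > delay_limit:
            raise ValueError(
                f"planted delay {e.delay} exceeds the configured delay limit {delay_limit}"
            )
        if not 0.0 < e.rho <= 1.0:
            raise ValueError("rho must be in (0, 1]")
        if e.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        edges.append(e)

    core_ids = [f"core{k:03d}" for k in range(n_core)]
    core_set = set(core_ids)
    for e in edges:
        if e.otu_a not in core_set or e.otu_b not in core_set:
            raise ValueError("planted edges must connect core OTUs")

    ss = np.random.SeedSequence(seed)
    lake_seeds = ss.spawn(n_lakes)
    rng_profiles = np.random.default_rng(ss.spawn(1)[0])
    # shared seasonal profile parameters for the core community
    t_axis = np.arange(1, n_times + 1, dtype=float)
    core_base = rng_profiles.normal(0.0, 0.5, size=n_core)
    core_amp = rng_profiles.uniform(1.0, 2.0, size=n_core)
    core_peak = rng_profiles.uniform(1.0, n_times, size=n_core)
    core_width = rng_profiles.uniform(2.0, 4.0, size=n_core)

    tables: dict[str, OtuTable] = {}
    latents: dict[str, tuple] = {}
    noncore_map: dict[str, set] = {}
    meta_rows = []

    for li, lake in enumerate(lakes):
        rng = np.random.default_rng(lake_seeds[li])
        noncore_ids = [f"{lake}_otu{k:03d}" for k in range(n_noncore_per_lake)]
        noncore_map[lake] = set(noncore_ids)
        otu_ids = core_ids + noncore_ids

        # latents on a time axis extended by one step on each side, so a
        # lagged coupling can reference real (not clamped) source values at
        # the window boundaries
        t_ext = np.arange(0, n_times + 2, dtype=float)
        core_bump_ext = core_amp[:, None] * np.exp(
            -((t_ext[None, :] - core_peak[:, None]) ** 2)
            / (2.0 * core_width[:, None] ** 2)
        )
        core_latent_ext = (
            core_base[:, None]
            + core_bump_ext
            + rng.normal(0.0, sigma, size=(n_core, n_times + 2))
        )
        core_latent = core_latent_ext[:, 1:-1].copy()
        non_latent, _ = _seasonal_latent(rng, n_noncore_per_lake, n_times, sigma)

        latent = np.vstack([core_latent, non_latent])
        index = {o: i for i, o in enumerate(otu_ids)}
        # impose planted couplings on the latent series
        for e in edges:
            src_ext = _standardize(core_latent_ext[index[e.otu_a]])
            # observed time t (1..n_times) reads the source at t - delay,
            # which stays inside the extended axis for |delay| <= 1
            shifted = src_ext[np.arange(1, n_times + 1) - e.delay]
            w = rng.normal(0.0, sigma, size=n_times)
            anomaly = e.rho * e.sign * shifted + np.sqrt(1.0 - e.rho**2) * w
            b = index[e.otu_b]
            # the coupled anomaly replaces b's seasonal bump; keep half the
            # bump amplitude as a baseline lift so targets are not
            # systematically rarer than bump-carrying OTUs
            latent[b] = core_base[b] + 0.5 * core_amp[b] + coupling_scale * anomaly

        latents[lake] = (list(otu_ids), latent.copy())
        comp = np.exp(latent)  # n_otus x n_times, unnormalized composition
        comp = comp / comp.sum(axis=0, keepdims=True)

        miss, phi = desiccation.get(lake, (frozenset(), 0.0))
        refill_from = None
        if miss:
            first_gap = min(miss)
            after = [t for t in range(first_gap + 1, n_times + 1) if t not in miss]
            refill_from = after[0] if after else None

        counts_rows = []
        kept_samples = []
        for t in range(1, n_times + 1):
            sid = f"{lake}_t{t:02d}"
            missing = t in miss
            meta_rows.append(
                {
                    "sample_id": sid,
                    "lake": lake,
                    "time_index": t,
                    "season": season_of(t, season_partition),
                    "missing": missing,
                }
            )
            if missing:
                continue
            p = comp[:, t - 1].copy()
            if refill_from is not None and t >= refill_from and phi > 0:
                non_idx = np.array([index[o] for o in noncore_ids])
                q = np.zeros_like(p)
                q[non_idx] = comp[non_idx, t - 1]
                if q.sum() == 0:
                    q[non_idx] = 1.0
                q = q / q.sum()
                p = (1.0 - phi) * p + phi * q
            if overdispersion is not None:
                p = rng.dirichlet(np.maximum(overdispersion * p, 1e-12))
            counts_rows.append(rng.multinomial(depth, p))
            kept_samples.append(sid)

        tables[lake] = OtuTable(
            pd.DataFrame(np.array(counts_rows), index=kept_samples, columns=otu_ids),
            unit="counts",
        )

    meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
    metadata = SampleMetadata(meta_df)
    truth = SyntheticTruth(
        core_otus=core_set,
        noncore_map=noncore_map,
        planted_edges=edges,
        seasonal_profiles={
            o: (float(core_peak[i]), float(core_width[i]), float(core_amp[i]))
            for i, o in enumerate(core_ids)
        },
        desiccation=desiccation,
        seed=seed,
    )
    params = {
        "n_lakes": n_lakes,
        "n_times": n_times,
        "n_core": n_core,
        "n_noncore_per_lake": n_noncore_per_lake,
        "depth": depth,
        "sigma": sigma,
        "coupling_scale": coupling_scale,
        "seed": seed,
        "overdispersion": overdispersion,
    }
    return SyntheticStudy(
        tables=tables, metadata=metadata, truth=truth, params=params, latents=latents
    )


def _even_partition(n_times):
    """Split 1..n_times into three contiguous season blocks."""
    a = max(1, n_times // 3)
    b = max(a + 1, 2 * n_times // 3)
    return {"spring": (1, a), "summer": (a + 1, b), "autumn": (b + 1, n_times)}


def planted_edge_catalogue(truth: SyntheticTruth) -> pd.DataFrame:
    """Canonical planted edge list for comparison with inferred networks.

    Members are ordered lexicographically (delay sign flipped on swap);
    duplicate pairs collapse to the record with the strongest coupling.
    """
    best: dict[tuple, PlantedEdge] = {}
    for e in truth.planted_edges:
        c = e.canonical()
        key = (c.otu_a, c.otu_b)
        if key not in best or c.rho > best[key].rho:
            best[key] = c
    rows = [
        {
            "otu_a": e.otu_a,
            "otu_b": e.otu_b,
            "sign": e.sign,
            "delay": e.delay,
            "rho": e.rho,
        }
        for e in sorted(best.values(), key=lambda e: (e.otu_a, e.otu_b))
    ]
    return pd.DataFrame(rows, columns=["otu_a", "otu_b", "sign", "delay", "rho"])


def match_planted_edges(edge_table: pd.DataFrame, truth: SyntheticTruth) -> pd.DataFrame:
    """Join an inferred association table against the planted catalogue.

    Inferred edges store the dynamic-programming delay convention
    ``d = start_x - start_y`` for the canonically ordered pair, which is the
    *negative* of the planted "b trails a by delay" convention; the join
    negates accordingly.  Returns the catalogue with columns ``recovered``,
    ``sign_ok`` and ``delay_class_ok`` (synchronous vs time-shifted).
    """
    cat = planted_edge_catalogue(truth)
    inferred = {}
    for _, row in edge_table.iterrows():
        a, b = sorted((row["otu_a"], row["otu_b"]))
        d = int(row["delay"])
        s = int(row["sign"])
        if (row["otu_a"], row["otu_b"]) != (a, b):
            d = -d
        inferred[(a, b)] = (s, d)
    rec, sign_ok, class_ok = [], [], []
    for _, row in cat.iterrows():
        hit = inferred.get((row["otu_a"], row["otu_b"]))
        rec.append(hit is not None)
        if hit is None:
            sign_ok.append(False)
            class_ok.append(False)
        else:
            s, d = hit
            sign_ok.append(s == row["sign"])
            # planted delay is -DP delay for the same ordered pair
            class_ok.append((d == 0) == (row["delay"] == 0))
    cat["recovered"] = rec
    cat["sign_ok"] = sign_ok
    cat["delay_class_ok"] = class_ok
    return cat


def write_truth(truth: SyntheticTruth, edge_path, manifest_path) -> None:
    """Write the planted-edge TSV and a JSON run manifest."""
    planted_edge_catalogue(truth).to_csv(edge_path, sep="\t", index=False)
    with open(manifest_path, "w") as fh:
        json.dump(truth.manifest(), fh, indent=2, sort_keys=True)
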