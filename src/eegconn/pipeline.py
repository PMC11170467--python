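"""Metric registry, region table, configuration, file I/O and the
end-to-end pipeline: simulate -> connectivity -> select -> classify.

The default registry enumerates 4 frequency-domain families x 3 variants
(instantaneous/lagged/total) x 8 bands plus the 5 broadband time-domain
metrics = 101 metric configurations.  The packaged region table mirrors the
82-region AAL cortical parcellation (41 regions per hemisphere) with lobe
codes F/L/O/P/T.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import selection as _selection
from .core import ConnectivityTensor, RegionTimeSeries, pair_index
from .spectral import (DEFAULT_BANDS, DEFAULT_EPOCH_LEN,
                       estimate_banded_cross_spectra, pairwise_triples)
from .synth import CohortSpec, Coupling, generate_cohort, write_subject, write_truth
from .timedomain import TIMEDOMAIN_METRICS, timedomain_edge_values

__all__ = [
    "metric_registry",
    "load_region_table",
    "RunConfig",
    "aggregate_voxels",
    "compute_connectivity",
    "connectivity_tensor",
    "write_tensor_tsv",
    "read_tensor_tsv",
    "run_pipeline",
]

logger = logging.getLogger("eegconn")

FAMILIES = ("LC", "Coh", "nLC", "PS")
VARIANTS = ("instantaneous", "lagged", "total")


def metric_registry(bands=DEFAULT_BANDS) -> pd.DataFrame:
    """Enumerate every metric configuration with a stable id.

    Frequency-domain ids are ``family:variant:band``; time-domain ids are
    ``metric:broadband``.  The default registry has
    4 x 3 x 8 + 5 = 101 entries.
    """
    rows = []
    for family in FAMILIES:
        for variant in VARIANTS:
            for band in bands:
                rows.append({"id": f"{family}:{variant}:{band.name}",
                             "family": family, "variant": variant,
                             "band": band.name, "domain": "frequency"})
    for metric in TIMEDOMAIN_METRICS:
        rows.append({"id": f"{metric}:broadband", "family": metric,
                     "variant": "value", "band": "broadband",
                     "domain": "time"})
    df = pd.DataFrame(rows)
    if df["id"].duplicated().any():
        raise RuntimeError("registry ids must be unique")
    return df


def load_region_table(path: str | Path | None = None) -> pd.DataFrame:
    """Region table (name, abbreviation, hemisphere, lobe).  The packaged
    default mirrors the 82-region AAL cortical parcellation."""
    if path is None:
        ref = resources.files("eegconn.data") / "aal82_regions.tsv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    required = {"name", "abbreviation", "hemisphere", "lobe"}
    if not required.issubset(table.columns):
        raise ValueError(f"region table must have columns {sorted(required)}")
    if table["abbreviation"].duplicated().any():
        raise ValueError("region abbreviations must be unique")
    return table


def aggregate_voxels(voxel_data: np.ndarray, voxel_regions: list[str],
                     fs: float, region_order: list[str] | None = None,
                     ) -> RegionTimeSeries:
    """Average voxel series into one mean series per region.

    ``voxel_data`` is (n_voxels, n_samples); ``voxel_regions`` assigns each
    voxel to exactly one region.  A region listed in ``region_order`` with
    no member voxels is an error.
    """
    voxel_data = np.atleast_2d(np.asarray(voxel_data, dtype=float))
    if len(voxel_regions) != voxel_data.shape[0]:
        raise ValueError("one region label per voxel required")
    order = region_order or list(dict.fromkeys(voxel_regions))
    rows = []
    labels = np.asarray(voxel_regions)
    for region in order:
        members = voxel_data[labels == region]
        if members.shape[0] == 0:
            raise ValueError(f"region {region!r} has zero voxels")
        rows.append(members.mean(axis=0))
    return RegionTimeSeries(np.vstack(rows), fs=fs, region_ids=list(order))


# ---------------------------------------------------------------------------
# Connectivity over the whole registry
# ---------------------------------------------------------------------------

def compute_connectivity(ts: RegionTimeSeries, bands=DEFAULT_BANDS,
                         epoch_len: float = DEFAULT_EPOCH_LEN,
                         ) -> dict[str, np.ndarray]:
    """One subject's value for every metric configuration: condensed pair
    vectors keyed by registry id."""
    cs = estimate_banded_cross_spectra(ts, bands=bands, epoch_len=epoch_len)
    values: dict[str, np.ndarray] = {}
    for family in FAMILIES:
        source = cs.S if family in ("LC", "Coh") else cs.S_norm
        for band in bands:
            triples = pairwise_triples(source[band.name], family)
            for variant in VARIANTS:
                values[f"{family}:{variant}:{band.name}"] = triples[variant]
    for metric, vec in timedomain_edge_values(ts.data).items():
        values[f"{metric}:broadband"] = vec
    return values


def connectivity_tensor(subjects: list[RegionTimeSeries], bands=DEFAULT_BANDS,
                        epoch_len: float = DEFAULT_EPOCH_LEN,
                        ) -> ConnectivityTensor:
    """Stack per-subject connectivity into (n_subjects, n_pairs) arrays."""
    if not subjects:
        raise ValueError("no subjects")
    per_subject = [compute_connectivity(ts, bands, epoch_len)
                   for ts in subjects]
    values = {config: np.vstack([d[config] for d in per_subject])
              for config in per_subject[0]}
    return ConnectivityTensor(
        values=values,
        subjects=[ts.subject_id or f"S{i + 1}" for i, ts in enumerate(subjects)],
        groups=[ts.group or "unknown" for ts in subjects],
        region_ids=list(subjects[0].region_ids))


def write_tensor_tsv(tensor: ConnectivityTensor, path: str | Path) -> None:
    """Long-format TSV: subject, group, metric_family, variant, band,
    region_a, region_b, value (regions 1-based)."""
    iu, ju = pair_index(tensor.n_regions)
    frames = []
    for config, values in sorted(tensor.values.items()):
        parts = config.split(":")
        family, variant, band = (parts if len(parts) == 3
                                 else (parts[0], "value", parts[1]))
        n_sub, n_edge = values.shape
        frames.append(pd.DataFrame({
            "subject": np.repeat(tensor.subjects, n_edge),
            "group": np.repeat(tensor.groups, n_edge),
            "metric_family": family, "variant": variant, "band": band,
            "region_a": np.tile(iu + 1, n_sub),
            "region_b": np.tile(ju + 1, n_sub),
            "value": values.ravel()}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_tensor_tsv(path: str | Path) -> ConnectivityTensor:
    df = pd.read_csv(path, sep="\t")
    subjects = list(dict.fromkeys(df["subject"]))
    groups = [df.loc[df["subject"] == s, "group"].iloc[0] for s in subjects]
    n_regions = int(df[["region_a", "region_b"]].to_numpy().max())
    iu, ju = pair_index(n_regions)
    n_edge = iu.size
    values = {}
    sub_pos = {s: i for i, s in enumerate(subjects)}
    for (family, variant, band), g in df.groupby(
            ["metric_family", "variant", "band"], sort=False):
        config = (f"{family}:{variant}:{band}" if variant != "value"
                  else f"{family}:{band}")
        arr = np.empty((len(subjects), n_edge))
        for s, gs in g.groupby("subject", sort=False):
            arr[sub_pos[s]] = gs["value"].to_numpy()
        values[config] = arr
    return ConnectivityTensor(values, subjects, groups,
                              [f"R{i + 1}" for i in range(n_regions)])


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration for one end-to-end run."""

    out_dir: str = "eegconn_run"
    seed: int = 0
    n_regions: int = 16
    n_subjects_per_group: tuple[int, int] = (10, 10)
    fs: float = 256.0
    duration: float = 60.0
    mixing_strength: float = 0.1
    noise_sd: float = 1.0
    couplings: list[dict] = field(default_factory=list)
    epoch_len: float = DEFAULT_EPOCH_LEN
    n_perm: int = _selection.DEFAULT_N_PERM
    alpha: float = _selection.DEFAULT_ALPHA
    scheme: str = "complementary_frequency"
    family: str = "Coh"
    variant: str = "lagged"
    search_budget: int = _classify.DEFAULT_SEARCH_BUDGET
    n_boot: int = _classify.DEFAULT_N_BOOT

    def __post_init__(self) -> None:
        # canonical JSON-stable form: pairs as lists, subject counts a tuple
        self.couplings = [{**c, "pair": list(c["pair"])}
                          for c in self.couplings]
        self.n_subjects_per_group = tuple(self.n_subjects_per_group)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_regions=self.n_regions,
            n_subjects_per_group=tuple(self.n_subjects_per_group),
            fs=self.fs, duration=self.duration,
            band_couplings=[Coupling(pair=tuple(c["pair"]), band=c["band"],
                                     group=c["group"],
                                     strength=c["strength"],
                                     lag=c.get("lag", 2))
                            for c in self.couplings],
            mixing_strength=self.mixing_strength, noise_sd=self.noise_sd,
            seed=self.seed)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data["n_subjects_per_group"] = tuple(data["n_subjects_per_group"])
        return cls(**data)


def default_couplings() -> list[dict]:
    """The default planted effects: band-specific hypo- and hyper-coupled
    pairs plus broadband covariance differences, on a 16-region cohort."""
    # lags sit near a quarter period of each band center so the planted
    # dependence is predominantly lagged rather than instantaneous
    return [
        # hypo: coupling present in controls only
        {"pair": (0, 1), "band": "alpha1", "group": "control",
         "strength": 0.9, "lag": 7},
        {"pair": (2, 3), "band": "theta", "group": "control",
         "strength": 0.9, "lag": 11},
        {"pair": (4, 5), "band": "beta1", "group": "control",
         "strength": 0.9, "lag": 4},
        # hyper: coupling present in patients only
        {"pair": (6, 7), "band": "alpha2", "group": "patient",
         "strength": 0.9, "lag": 6},
        {"pair": (8, 9), "band": "delta", "group": "patient",
         "strength": 0.9, "lag": 23},
        # broadband (time-domain) effects
        {"pair": (10, 11), "band": "broadband", "group": "control",
         "strength": 0.8, "lag": 0},
        {"pair": (12, 13), "band": "broadband", "group": "patient",
         "strength": 0.8, "lag": 0},
    ]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write all artifacts to ``config.out_dir``.

    Outputs: per-subject TSV matrices + sidecars, planted-truth edge list,
    the long-format connectivity TSV, consistency tables (pair and region),
    the classification report JSON and a manifest of stages and seeds.
    Bit-reproducible given the same config (timestamps aside).
    """
    if config.scheme not in _classify.SCHEMES:
        raise ValueError(f"unknown scheme {config.scheme!r}")
    if config.family not in FAMILIES:
        raise ValueError(f"unknown metric family {config.family!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "seed": config.seed}
    current = {"name": "init"}

    def stage(name: str):
        current["name"] = name
        t0 = time.perf_counter()

        def done():
            dt = time.perf_counter() - t0
            logger.info("stage %s finished in %.2f s", name, dt)
            manifest["stages"].append({"name": name, "seconds": round(dt, 3)})
        return done

    try:
        done = stage("simulate")
        subjects, truth = generate_cohort(config.cohort_spec())
        sim_dir = out / "subjects"
        sim_dir.mkdir(exist_ok=True)
        for ts in subjects:
            write_subject(ts, sim_dir / f"{ts.subject_id}.tsv")
        write_truth(truth, out / "planted_truth.tsv")
        done()

        done = stage("connectivity")
        tensor = connectivity_tensor(subjects, epoch_len=config.epoch_len)
        write_tensor_tsv(tensor, out / "connectivity.tsv")
        done()

        done = stage("select")
        results = _selection.select_edges(
            tensor, n_perm=config.n_perm, alpha=config.alpha,
            seed=config.seed)
        table = _selection.build_consistency(results, tensor.n_regions)
        pair_out = table.pair_counts.copy()
        pair_out[["region_a", "region_b"]] += 1
        pair_out.to_csv(out / "consistency_pairs.tsv", sep="\t", index=False)
        region_out = table.region_scores.copy()
        region_out["region"] += 1
        region_out.to_csv(out / "consistency_regions.tsv", sep="\t",
                          index=False)
        done()

        done = stage("classify")
        survivors = [r for r in results if r.passes_fdr]
        fm = _classify.assemble_features(
            tensor, survivors, config.scheme, family=config.family,
            variant=config.variant)
        report, _model = _classify.train_and_evaluate(
            fm, seed=config.seed, search_budget=config.search_budget,
            n_boot=config.n_boot)
        (out / "classification.json").write_text(json.dumps({
            "scheme": config.scheme, "family": config.family,
            "variant": config.variant,
            "scores": {k: list(v) for k, v in report.scores.items()},
            "test_scores": report.test_scores,
            "auc": report.auc,
            "selected_features": report.selected_features.to_dict("records"),
        }, indent=2))
        done()
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {current['name']!r} failed: {err}") from err

    manifest["n_configs"] = len(tensor.values)
    manifest["n_survivor_cells"] = int(sum(r.passes_fdr for r in results))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
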