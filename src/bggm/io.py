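"""Readers and writers for the package's file artifacts, plus the pipeline
runner used by the command-line interface.

All matrices travel as delimited text (comma or tab, autodetected) with one
header row of region labels.  Posterior graph samples are stored as
upper-triangle bitstrings, one retained draw per line — compact, diff-able and
language-neutral; precision draws are stored as a single stacked array file
with a JSON index sidecar.  Each run writes a manifest (config + seed +
package version) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import Graph, PrecisionMatrix, TimeSeriesData
from .evaluation import GroundTruth, reconstruction_errors
from .fusion import StreamlineCounts
from .mcmc import PosteriorSamples
from .model import GraphicalModel
from .priors import EdgePrior, RegionAnnotation, homotopy_prior

__all__ = [
    "read_matrix", "write_matrix", "read_region_annotation", "RunConfig",
    "run_pipeline", "write_samples", "read_samples",
]

logger = logging.getLogger("bggm")


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def _read_frame(path: str | Path) -> pd.DataFrame:
    # explicit delimiter detection keeps the C parser (and its round-trip
    # float handling) available, so written matrices re-read bit-identically
    frame = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected a delimited matrix with at least 2 columns")
    return frame


def read_matrix(path: str | Path, kind: str):
    """Read a typed matrix: ``timeseries``, ``counts``, ``prior`` or ``mask``.

    Validation errors name the offending cell where possible.
    """
    frame = _read_frame(path)
    labels = tuple(str(c) for c in frame.columns)
    values = frame.to_numpy()
    if kind == "timeseries":
        return TimeSeriesData(values.astype(float), labels)
    if kind == "counts":
        arr = np.asarray(values)
        bad = np.argwhere(~np.isfinite(arr.astype(float)) | (arr.astype(float) % 1 != 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(f"{path}: non-integer count at row {i}, column '{labels[j]}'")
        return StreamlineCounts(arr.astype(np.int64), labels)
    if kind == "prior":
        arr = values.astype(float)
        bad = np.argwhere((arr < 0) | (arr > 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"{path}: prior probability {arr[tuple(bad[0])]} outside [0, 1] "
                f"at row {i}, column '{labels[j]}'"
            )
        return EdgePrior(arr)
    if kind == "mask":
        arr = values.astype(float)
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError(f"{path}: mask entries must be 0 or 1")
        return arr.astype(np.int8)
    raise ValueError(f"unknown matrix kind '{kind}'")


def write_matrix(path: str | Path, values: np.ndarray, labels=None) -> None:
    p = np.asarray(values).shape[1]
    labels = list(labels) if labels is not None else [f"region_{i}" for i in range(p)]
    pd.DataFrame(np.asarray(values), columns=labels).to_csv(path, index=False)


def read_region_annotation(path: str | Path,
                           homotopy_path: str | Path | None = None
                           ) -> tuple[RegionAnnotation, tuple[str, ...]]:
    """Two-column file (region label, hemisphere) plus an optional two-column
    homotopy-pair list of region labels."""
    frame = pd.read_csv(path, sep=None, engine="python", header=None,
                        names=["region", "hemisphere"])
    labels = tuple(str(r) for r in frame["region"])
    index = {lab: i for i, lab in enumerate(labels)}
    pairs: dict[int, int] = {}
    if homotopy_path is not None:
        hp = pd.read_csv(homotopy_path, sep=None, engine="python", header=None)
        for _, row in hp.iterrows():
            a, b = index[str(row.iloc[0])], index[str(row.iloc[1])]
            pairs[a] = b
            pairs[b] = a
    ann = RegionAnnotation(tuple(frame["hemisphere"]), pairs)
    return ann, labels


# ---------------------------------------------------------------------------
# posterior sample files


def write_samples(directory: str | Path, samples: PosteriorSamples, labels) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "graphs.txt").write_text("\n".join(samples.bitstrings()) + "\n")
    stack = samples.precision_stack()
    t, p, _ = stack.shape
    np.savetxt(directory / "precisions.txt", stack.reshape(t * p, p))
    index = {
        "n_samples": t,
        "p": p,
        "region_labels": list(labels),
        "chain_id": [int(c) for c in np.asarray(samples.meta.get("chain_id", []))],
        "meta": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in samples.meta.items() if k != "chain_id"},
    }
    (directory / "precisions.index.json").write_text(json.dumps(index, indent=2))


def read_samples(directory: str | Path) -> PosteriorSamples:
    directory = Path(directory)
    index = json.loads((directory / "precisions.index.json").read_text())
    t, p = index["n_samples"], index["p"]
    stack = np.loadtxt(directory / "precisions.txt").reshape(t, p, p)
    bits = (directory / "graphs.txt").read_text().split()
    graphs = [Graph.from_bitstring(b, p) for b in bits]
    precisions = [PrecisionMatrix(0.5 * (stack[i] + stack[i].T), graphs[i]) for i in range(t)]
    meta = dict(index.get("meta", {}))
    meta["chain_id"] = np.asarray(index.get("chain_id", [0] * t))
    return PosteriorSamples(graphs, precisions, meta)


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Structured configuration for a full inference run (YAML or JSON)."""

    timeseries: str
    output_dir: str
    streamlines: str | None = None
    theta: float = 0.5
    theta_file: str | None = None
    hemisphere_file: str | None = None
    homotopy_file: str | None = None
    delta: float = 3.0
    D_file: str | None = None
    alpha: float = 1.0
    beta: float = 0.5
    n_iterations: int = 50_000
    burn_in: int | None = None
    thin_to: int = 1000
    n_chains: int = 2
    seed: int = 0
    standardize: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)  # YAML is a JSON superset: both are accepted
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _build_model(cfg: RunConfig) -> GraphicalModel:
    X = read_matrix(cfg.timeseries, "timeseries")
    if cfg.theta_file is not None:
        prior = read_matrix(cfg.theta_file, "prior")
    elif cfg.hemisphere_file is not None:
        ann, labels = read_region_annotation(cfg.hemisphere_file, cfg.homotopy_file)
        if labels != tuple(X.region_labels):
            raise ValueError("annotation region labels do not match the time series")
        prior = homotopy_prior(ann)
    else:
        prior = float(cfg.theta)
    streamlines = None
    if cfg.streamlines is not None:
        streamlines = read_matrix(cfg.streamlines, "counts")
    D = None
    if cfg.D_file is not None:
        D = _read_frame(cfg.D_file).to_numpy(dtype=float)
    return GraphicalModel(X, streamlines=streamlines, edge_prior=prior, delta=cfg.delta,
                          prior_scale=D, alpha=cfg.alpha, beta=cfg.beta,
                          standardize=cfg.standardize)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run inference per the config and write all artifacts to the output
    directory; returns that directory.

    Outputs: posterior samples (graph bitstrings + stacked precisions),
    summary matrices (edge probabilities, mean and variance of partial
    correlations), a diagnostics report (entropy, MAP probability, density,
    convergence), and a reproducibility manifest.  A failed convergence check
    is recorded as a warning — outputs are still written and flagged.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = _build_model(cfg)
    logger.info("fitting model: p=%d, n=%d, fused=%s", model.p, model.nobs,
                model.streamlines is not None)
    results = model.fit(n_iterations=cfg.n_iterations, burn_in=cfg.burn_in,
                        thin_to=cfg.thin_to, n_chains=cfg.n_chains, seed=cfg.seed)
    labels = model.data.region_labels
    write_samples(out / "samples", results.samples, labels)
    write_matrix(out / "edge_probabilities.csv", results.edge_probabilities, labels)
    write_matrix(out / "partial_correlations_mean.csv", results.partial_correlations, labels)
    write_matrix(out / "partial_correlations_var.csv", results.partial_correlation_variance,
                 labels)
    conv = results.convergence
    diagnostics = {
        "density": results.density,
        "entropy_bits": results.entropy,
        "map_probability": results.map_probability,
        "unique_fraction": results.unique_fraction,
        "acceptance_rate": results.samples.meta["acceptance_rate"],
        "convergence_max_discrepancy": None if conv is None else conv.max_discrepancy,
        "convergence_passed": None if conv is None else bool(conv.passed),
    }
    if conv is not None and not conv.passed:
        logger.warning("convergence check FAILED: %s", conv)
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    (out / "summary.txt").write_text(results.summary(top=None) + "\n")
    manifest = {
        "package": "bggm",
        "version": __version__,
        "mode": "fused" if model.streamlines is not None else "timeseries",
        "config": cfg.to_dict(),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out


def evaluate_files(r_star_path, mask_path, estimate_path) -> dict:
    """Reconstruction errors of a stored partial-correlation estimate against a
    stored ground truth."""
    from .data import PartialCorrelationMatrix

    r_star = _read_frame(r_star_path).to_numpy(dtype=float)
    mask = read_matrix(mask_path, "mask")
    estimate = _read_frame(estimate_path).to_numpy(dtype=float)
    truth = GroundTruth(PartialCorrelationMatrix(r_star), mask)
    scores = reconstruction_errors(truth, PartialCorrelationMatrix(estimate))
    return {"eta": scores.eta, "eta_tp": scores.eta_tp, "eta_tn": scores.eta_tn}
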