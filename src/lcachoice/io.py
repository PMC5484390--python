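"""Reading choice sets and parameter files, writing results and fixtures.

CSV conventions: comma-separated, header row, UTF-8, '.' decimal; floats are
serialized at 17 significant digits so round-trips are exact. Every CLI run
writes a manifest (config echo + seed + package version) next to its
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network import ChoiceSet, ChoiceProbabilities, NetworkParams
from .studies import StudyResult, generate_choice_sets

__all__ = [
    "load_choice_set",
    "load_params",
    "write_probabilities",
    "write_study_result",
    "write_manifest",
    "make_fixtures",
]

FLOAT_FORMAT = "%.17g"

#: the worked attribute vector used throughout the transform examples
CANONICAL_INPUTS = (0.75, 0.5, 0.25)
#: proportional attribute weights of the identification study
PROPORTIONAL_WEIGHTS = (0.03, 0.015, 0.01)
#: equal attribute weights of the identification study
EQUAL_WEIGHTS = (0.01, 0.01, 0.01)


def _load_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, dict):
        return config
    path = Path(config)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def load_choice_set(path, config=None) -> ChoiceSet:
    """Load a choice set from CSV (rows = alternatives, columns = attributes).

    Weights (and optionally an availability mask) come from ``config`` — a
    dict or a JSON/YAML sidecar path. Without a config, weights default to
    equal. Open-interval violations are reported with the offending cell.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"malformed choice-set CSV {path}: {exc}") from exc
    if frame.empty:
        raise ValueError(f"choice-set CSV {path} has no data rows")
    values = frame.to_numpy(dtype=float)
    cfg = _load_config(config)
    weights = cfg.get("weights")
    if weights is None:
        weights = np.full(values.shape[1], 1.0 / values.shape[1])
    weights = np.asarray(weights, dtype=float)
    if weights.size != values.shape[1]:
        raise ValueError(
            f"{weights.size} weights for {values.shape[1]} attribute columns in {path}"
        )
    available = cfg.get("available")
    return ChoiceSet(values=values, weights=weights, available=available)


def load_params(config) -> NetworkParams:
    """Network parameters from a JSON/YAML config (keys s_P, l_P, s_A, l_A, Q, ...)."""
    cfg = _load_config(config)
    known = {f.name for f in dataclasses.fields(NetworkParams)}
    unknown = set(cfg) - known - {"seed"}
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in cfg.items() if k in known}
    return NetworkParams(**kwargs)


def write_manifest(out_dir, command: str, config: dict, seed) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "package_version": __version__,
        "config": config,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def write_probabilities(result: ChoiceProbabilities, path) -> Path:
    """Choice probabilities as CSV (one row per alternative)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {
            "alternative": np.arange(result.probabilities.size),
            "probability": result.probabilities,
        }
    )
    try:
        frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    except OSError as exc:
        raise OSError(f"cannot write probabilities to {path}: {exc}") from exc
    return path


def write_study_result(result: StudyResult, out_dir, stem: str = "study") -> list[Path]:
    """Study result as CSV table(s) plus a JSON summary; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {"seed": result.seed, "config": result.config}
    if result.accuracy is not None:
        path = out_dir / f"{stem}_accuracy.csv"
        result.accuracy.rename_axis("preset").to_csv(path, float_format=FLOAT_FORMAT)
        written.append(path)
        summary["evaluated_set_counts"] = result.evaluated_set_counts
    if result.uniqueness_curve is not None:
        path = out_dir / f"{stem}_uniqueness.csv"
        rows = [
            {"n_sets": n, "n_unique": k, "n_combos": total,
             "proportion": k / total}
            for n, (k, total) in sorted(result.uniqueness_curve.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)
        written.append(path)
    jpath = out_dir / f"{stem}_summary.json"
    jpath.write_text(json.dumps(summary, indent=2, default=str) + "\n")
    written.append(jpath)
    return written


def make_fixtures(seed: int, out_dir=None, n_sets: int = 10) -> dict:
    """Canonical small inputs for tests and demos.

    Returns (and optionally writes) the worked attribute vector
    (0.75, 0.5, 0.25), the study weight sets, and a deterministic batch of
    uniform 3x3 choice sets drawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    sets = generate_choice_sets(n_sets, 3, 3, rng, weights=PROPORTIONAL_WEIGHTS)
    fixtures = {
        "canonical_inputs": np.asarray(CANONICAL_INPUTS),
        "proportional_weights": np.asarray(PROPORTIONAL_WEIGHTS),
        "equal_weights": np.asarray(EQUAL_WEIGHTS),
        "choice_sets": sets,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"value": fixtures["canonical_inputs"]}).to_csv(
            out_dir / "canonical_inputs.csv", index=False, float_format=FLOAT_FORMAT
        )
        pd.DataFrame(
            {
                "proportional": fixtures["proportional_weights"],
                "equal": fixtures["equal_weights"],
            }
        ).to_csv(out_dir / "weights.csv", index=False, float_format=FLOAT_FORMAT)
        for i, cs in enumerate(sets):
            pd.DataFrame(
                cs.values, columns=[f"attr_{j+1}" for j in range(cs.n_attributes)]
            ).to_csv(out_dir / f"choice_set_{i:02d}.csv", index=False,
                     float_format=FLOAT_FORMAT)
    return fixtures
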