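"""Saving and loading fitted models.

Models are stored with :mod:`joblib` as a single file holding a header
dict (format tag, package version, training metadata) next to the fitted
estimator, so a loaded file can be inspected and validated before use.
"""

from __future__ import annotations

from pathlib import Path

import joblib

_FORMAT = "rotimb-model"
_VERSION = 1


def save_model(model, path: str | Path) -> None:
    """Write a fitted ensemble to ``path``."""
    payload = {
        "format": _FORMAT,
        "version": _VERSION,
        "meta": dict(getattr(model, "meta", {})),
        "n_features": getattr(model, "n_features", None),
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path):
    """Load a model written by :func:`save_model`."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != _FORMAT:
        raise ValueError(f"{path} is not a saved model file")
    return payload["model"]
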