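"""Plain-text readers/writers for decays, spectra and fit results.

Decay CSV: columns ``t_us,intensity`` with metadata as ``# key=value``
header comments.  Spectrum CSV: ``field_gauss,amplitude`` plus a
``# temperature_label=...`` comment.  Fit results serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sr import SRDecay, SRFitResult
from .spectra import Spectrum

__all__ = [
    "write_decay_csv",
    "read_decay_csv",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "fit_result_to_dict",
    "write_fit_json",
]


def _read_comments(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_decay_csv(decay: SRDecay, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in decay.meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("t_us,intensity\n")
        np.savetxt(fh, np.column_stack([decay.t, decay.intensity]),
                   delimiter=",", fmt="%.10g")


def read_decay_csv(path: str | Path) -> SRDecay:
    path = Path(path)
    meta = _read_comments(path)
    df = pd.read_csv(path, comment="#")
    return SRDecay(t=df["t_us"].to_numpy(), intensity=df["intensity"].to_numpy(),
                   meta=meta)


def write_spectrum_csv(spec: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# temperature_label={spec.temperature_label}\n")
        fh.write("field_gauss,amplitude\n")
        np.savetxt(fh, np.column_stack([spec.field, spec.amplitude]),
                   delimiter=",", fmt="%.10g")


def read_spectrum_csv(path: str | Path) -> Spectrum:
    path = Path(path)
    meta = _read_comments(path)
    df = pd.read_csv(path, comment="#")
    return Spectrum(
        field=df["field_gauss"].to_numpy(),
        amplitude=df["amplitude"].to_numpy(),
        temperature_label=meta.get("temperature_label", "fluid_37C"),
    )


def fit_result_to_dict(fit: SRFitResult) -> dict:
    return {
        "n_components": fit.n_components,
        "params": dict(fit.params),
        "se": dict(fit.se),
        "rss": fit.rss,
        "aicc": fit.aicc,
        "n_points": fit.n_points,
        "converged": fit.converged,
        "degenerate": fit.degenerate,
    }


def write_fit_json(fit: SRFitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit), indent=2))
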