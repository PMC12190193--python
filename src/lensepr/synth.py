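"""Seeded synthetic datasets emulating the lens-membrane EPR experiments.

Every stage of the pipeline is testable without instrument data: this
module generates saturation-recovery decay pairs (air/N2), fluid and frozen
CW spectra, Chol/PL titration series, and full per-species scenarios with
ground-truth sidecars for parameter-recovery tests.

The depth templates are *invented plumbing with qualitative shapes taken
from the science*, not digitized experimental values:

* without Chol, OTP and fluidity rise smoothly toward the membrane center
  (bell-shaped once symmetrized over both leaflets) and the chain order
  parameter falls with depth;
* with Chol at or above the saturation limit, OTP is suppressed down to
  carbon C9 (the reach of the rigid sterol ring) and then jumps ~3x
  between C9 and C10;
* the center OTP of Chol-containing membranes decreases from mouse to pig
  to human (the lifespan trend);
* oversaturated membranes add a cholesterol-bilayer-domain (CBD)
  environment at the membrane center with a smaller OTP than the bulk,
  producing a two-component air recovery for the ASL label.

Default template magnitudes (e.g. bulk center OTP ~0.6 1/us saturated,
CBD ~0.25 1/us) are physically plausible round numbers.  Noise defaults to
1% of the decay amplitude; all randomness flows from one seed per scenario.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .composition import PLComposition, load_species_presets
from .oximetry import TitrationPoint, TitrationSeries
from .sr import SRDecay, simulate_sr_decay
from .spectra import Spectrum, simulate_axial_spectrum, default_tensor
from . import io as _io

__all__ = [
    "ScenarioSpec",
    "ScenarioDataset",
    "make_decay_pair",
    "make_titration",
    "make_species_scenario",
    "write_scenario",
    "OTP_TEMPLATES",
    "RATE_N2_TEMPLATE",
    "CBD_W_CENTER",
]

SPECIES = ("mouse", "pig", "human")
CONDITIONS = ("no_chol", "saturated", "oversaturated")

#: oxygen-free spin-lattice relaxation rate (1/us) per depth label —
#: a gentle rise toward the fluid membrane center
RATE_N2_TEMPLATE: Mapping[str, float] = {
    "T-PC": 0.12, "CSL": 0.12, "5-PC": 0.14, "7-PC": 0.16, "9-SASL": 0.18,
    "10-PC": 0.20, "12-PC": 0.22, "14-PC": 0.24, "16-PC": 0.26,
    "ASL-center": 0.26,
}

#: species-dependent center OTP for Chol-containing membranes (1/us):
#: largest Chol-induced increase for mouse, least for human
_CENTER_W = {"mouse": 0.80, "pig": 0.72, "human": 0.64}

#: bulk OTP (1/us) per depth.  no_chol is bell-shaped toward the center;
#: saturated/oversaturated are Chol-suppressed to C9 with a 3.0x step
#: between C9 and C10.
OTP_TEMPLATES: Mapping[str, Mapping[str, Mapping[str, float]]] = {
    sp: {
        "no_chol": {
            "T-PC": 0.25, "CSL": 0.25, "5-PC": 0.35, "7-PC": 0.45,
            "9-SASL": 0.55, "10-PC": 0.62, "12-PC": 0.72, "14-PC": 0.82,
            "16-PC": 0.90, "ASL-center": 0.90,
        },
        **{
            cond: {
                "T-PC": 0.10, "CSL": 0.10, "5-PC": 0.14, "7-PC": 0.17,
                "9-SASL": 0.20, "10-PC": 0.60, "12-PC": 0.66, "14-PC": 0.72,
                "16-PC": _CENTER_W[sp], "ASL-center": _CENTER_W[sp],
            }
            for cond in ("saturated", "oversaturated")
        },
    }
    for sp in SPECIES
}

#: CBD oxygen transport parameter at the membrane center (1/us)
CBD_W_CENTER = 0.25
#: amplitude fraction of the CBD component in oversaturated center decays
CBD_AMP_FRACTION = 0.40

#: fluid-phase observed splittings (gauss) per chain depth: order falls
#: with depth; Chol increases it at all depths
_FLUID_SPLITTINGS = {
    "no_chol": {
        "5-PC": (27.0, 9.5), "7-PC": (25.0, 10.0), "9-SASL": (23.0, 10.5),
        "10-PC": (21.5, 11.0), "12-PC": (20.0, 11.5), "14-PC": (18.5, 12.0),
        "16-PC": (17.0, 12.5),
    },
    "chol": {
        "5-PC": (31.0, 8.0), "7-PC": (29.5, 8.5), "9-SASL": (28.0, 9.0),
        "10-PC": (25.0, 9.8), "12-PC": (22.5, 10.6), "14-PC": (20.0, 11.4),
        "16-PC": (18.0, 12.2),
    },
}

#: frozen-sample maximum splitting 2A_Z (gauss): smaller = more hydrophobic.
#: Chol keeps the headgroup region polar and steps hydrophobicity up
#: (2A_Z down) between C9 and C10.
_TWO_AZ = {
    "no_chol": {
        "T-PC": 70.0, "5-PC": 67.0, "7-PC": 65.0, "9-SASL": 63.0,
        "10-PC": 62.0, "12-PC": 60.5, "14-PC": 59.0, "16-PC": 58.0,
    },
    "chol": {
        "T-PC": 72.0, "5-PC": 67.5, "7-PC": 66.5, "9-SASL": 66.0,
        "10-PC": 60.0, "12-PC": 58.5, "14-PC": 57.5, "16-PC": 57.0,
    },
}

DEPTH_LABELS = tuple(RATE_N2_TEMPLATE)


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one synthetic species/condition dataset."""

    species: str
    condition: str
    noise_sd: float = 0.01
    seed: int = 0
    template_params: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ScenarioDataset:
    """Generated scenario: decay pairs, spectra, composition, truth sidecar."""

    spec: ScenarioSpec
    composition: PLComposition
    decay_pairs: Mapping[str, tuple[SRDecay, SRDecay]]
    fluid_spectra: Mapping[str, Spectrum]
    frozen_spectra: Mapping[str, Spectrum]
    truth: Mapping[str, object] = dc_field(default_factory=dict)


def make_decay_pair(
    true_T1_air: float,
    true_T1_n2: float,
    noise_sd: float = 0.01,
    seed: int | np.random.SeedSequence | None = None,
    n_points: int = 2048,
    meta: Mapping[str, object] | None = None,
) -> tuple[SRDecay, SRDecay]:
    """Seeded air/N2 decay pair on a shared grid (5x the longer T1).

    ``noise_sd`` is relative to the unit decay amplitude.
    """
    if true_T1_air <= 0 or true_T1_n2 <= 0:
        raise ValueError("T1 values must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_air, s_n2 = ss.spawn(2)
    t = np.linspace(0.0, 5.0 * max(true_T1_air, true_T1_n2), n_points)
    meta = dict(meta or {})
    air = simulate_sr_decay(
        [(1.0, true_T1_air)], t_grid=t, noise_sd=noise_sd,
        seed=np.random.default_rng(s_air), meta={**meta, "atmosphere": "air"},
    )
    n2 = simulate_sr_decay(
        [(1.0, true_T1_n2)], t_grid=t, noise_sd=noise_sd,
        seed=np.random.default_rng(s_n2), meta={**meta, "atmosphere": "N2"},
    )
    return air, n2


def _center_decay_pair(
    w_bulk: float,
    w_cbd: float | None,
    rate_n2: float,
    noise_sd: float,
    ss: np.random.SeedSequence,
    cbd_fraction: float = CBD_AMP_FRACTION,
    n_points: int = 2048,
    meta: Mapping[str, object] | None = None,
) -> tuple[SRDecay, SRDecay]:
    """Air/N2 pair at the membrane center, optionally with a CBD component.

    The oxygen-free rate is shared by both environments, so the N2 decay is
    single-exponential even when CBDs are present.  Each decay is recorded
    on its own window spanning five times its longest T1, as an acquisition
    window is tuned per decay: air relaxes much faster than nitrogen.
    """
    s_air, s_n2 = ss.spawn(2)
    t1_n2 = 1.0 / rate_n2
    comps = [(1.0 - (cbd_fraction if w_cbd is not None else 0.0),
              1.0 / (rate_n2 + w_bulk))]
    if w_cbd is not None:
        comps.append((cbd_fraction, 1.0 / (rate_n2 + w_cbd)))
    t_air = np.linspace(0.0, 5.0 * max(t1 for _, t1 in comps), n_points)
    t_n2 = np.linspace(0.0, 5.0 * t1_n2, n_points)
    meta = dict(meta or {})
    air = simulate_sr_decay(
        comps, t_grid=t_air, noise_sd=noise_sd, seed=np.random.default_rng(s_air),
        meta={**meta, "atmosphere": "air"},
    )
    n2 = simulate_sr_decay(
        [(1.0, t1_n2)], t_grid=t_n2, noise_sd=noise_sd,
        seed=np.random.default_rng(s_n2), meta={**meta, "atmosphere": "N2"},
    )
    return air, n2


def make_titration(
    species: str,
    onset_ratio: float,
    ratios: Sequence[float],
    noise_sd: float = 0.01,
    seed: int = 0,
    spin_label: str = "ASL",
) -> TitrationSeries:
    """Chol/PL titration of an ASL (center) label with CBD onset.

    Points with mixing ratio below ``onset_ratio`` give single-component
    air recoveries at the bulk OTP; from the onset upward a CBD component
    appears (amplitude fraction 40%), with the bulk OTP constant and the
    CBD OTP slowly decreasing with ratio.
    """
    ratios = list(ratios)
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise ValueError("ratios must be strictly increasing")
    if onset_ratio < 0:
        raise ValueError("onset_ratio must be >= 0")
    tmpl = OTP_TEMPLATES[species]
    rate_n2 = RATE_N2_TEMPLATE["ASL-center"]
    w_bulk_chol = tmpl["saturated"]["ASL-center"]
    w_no_chol = tmpl["no_chol"]["ASL-center"]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ratios))
    points = []
    for r, child in zip(ratios, children):
        # bulk OTP interpolates from the Chol-free value at r=0 to the
        # Chol-suppressed... at the center Chol *raises* W; blend linearly
        # up to the onset, constant beyond (saturation pins bulk properties)
        frac = min(r / onset_ratio, 1.0) if onset_ratio > 0 else 1.0
        w_bulk = w_no_chol + frac * (w_bulk_chol - w_no_chol)
        w_cbd = None
        if r >= onset_ratio:
            w_cbd = max(CBD_W_CENTER - 0.02 * (r - onset_ratio), 0.15)
        air, n2 = _center_decay_pair(
            w_bulk, w_cbd, rate_n2, noise_sd, child,
            meta={"ratio": r, "label": spin_label, "species": species},
        )
        points.append(TitrationPoint(ratio=r, decay_air=air, decay_n2=n2))
    return TitrationSeries(points=points, spin_label=spin_label,
                           species_label=species)


def make_species_scenario(spec: ScenarioSpec) -> ScenarioDataset:
    """Full per-depth dataset for one species and Chol condition.

    Produces air/N2 decay pairs at every depth label, fluid spectra for the
    chain labels, frozen spectra for the 2A_Z labels, the species
    composition preset, and a ground-truth sidecar mirroring every
    generating parameter.  Identical specs give bitwise-identical data.
    """
    tmpl_otp = (
        spec.template_params
        if spec.template_params is not None
        else OTP_TEMPLATES[spec.species][spec.condition]
    )
    chol_key = "no_chol" if spec.condition == "no_chol" else "chol"
    composition = load_species_presets()[spec.species]
    ss = np.random.SeedSequence(spec.seed)
    children = iter(ss.spawn(len(DEPTH_LABELS) + len(_FLUID_SPLITTINGS[chol_key])
                             + len(_TWO_AZ[chol_key])))

    decay_pairs: dict[str, tuple[SRDecay, SRDecay]] = {}
    truth_w: dict[str, dict[str, float]] = {}
    for lbl in DEPTH_LABELS:
        rate_n2 = RATE_N2_TEMPLATE[lbl]
        w_bulk = tmpl_otp[lbl]
        has_cbd = spec.condition == "oversaturated" and lbl == "ASL-center"
        w_cbd = CBD_W_CENTER if has_cbd else None
        pair = _center_decay_pair(
            w_bulk, w_cbd, rate_n2, spec.noise_sd, next(children),
            meta={"label": lbl, "species": spec.species,
                  "condition": spec.condition},
        )
        decay_pairs[lbl] = pair
        truth_w[lbl] = {"W_bulk": w_bulk, "rate_n2": rate_n2}
        if w_cbd is not None:
            truth_w[lbl]["W_cbd"] = w_cbd

    tensor = default_tensor()
    fluid_spectra: dict[str, Spectrum] = {}
    truth_fluid: dict[str, dict[str, float]] = {}
    for lbl, (a_par, a_perp) in _FLUID_SPLITTINGS[chol_key].items():
        fluid_spectra[lbl] = simulate_axial_spectrum(
            a_par, a_perp, linewidth=1.0, noise_sd=spec.noise_sd,
            seed=np.random.default_rng(next(children)),
        )
        truth_fluid[lbl] = {"A_par": a_par, "A_perp": a_perp}

    frozen_spectra: dict[str, Spectrum] = {}
    truth_frozen: dict[str, float] = {}
    for lbl, two_az in _TWO_AZ[chol_key].items():
        frozen_spectra[lbl] = simulate_axial_spectrum(
            two_az / 2.0, (tensor.A_xx + tensor.A_yy) / 2.0, linewidth=1.5,
            temperature_label="frozen_minus165C", noise_sd=spec.noise_sd,
            seed=np.random.default_rng(next(children)),
        )
        truth_frozen[lbl] = two_az

    truth = {
        "species": spec.species,
        "condition": spec.condition,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "otp": truth_w,
        "fluid_splittings": truth_fluid,
        "two_Az": truth_frozen,
        "cbd_amp_fraction": CBD_AMP_FRACTION if spec.condition == "oversaturated" else 0.0,
    }
    return ScenarioDataset(
        spec=spec, composition=composition, decay_pairs=decay_pairs,
        fluid_spectra=fluid_spectra, frozen_spectra=frozen_spectra,
        truth=truth,
    )


def write_scenario(ds: ScenarioDataset, outdir: str | Path) -> Path:
    """Write a scenario to ``<outdir>/<species>_<condition>/`` as CSV/JSON."""
    root = Path(outdir) / f"{ds.spec.species}_{ds.spec.condition}"
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {"decays": {}, "fluid_spectra": {},
                                 "frozen_spectra": {}}
    for lbl, (air, n2) in ds.decay_pairs.items():
        fa = f"decay_{lbl}_air.csv"
        fn = f"decay_{lbl}_n2.csv"
        _io.write_decay_csv(air, root / fa)
        _io.write_decay_csv(n2, root / fn)
        manifest["decays"][lbl] = {"air": fa, "n2": fn}
    for lbl, spec_ in ds.fluid_spectra.items():
        f = f"spectrum_fluid_{lbl}.csv"
        _io.write_spectrum_csv(spec_, root / f)
        manifest["fluid_spectra"][lbl] = f
    for lbl, spec_ in ds.frozen_spectra.items():
        f = f"spectrum_frozen_{lbl}.csv"
        _io.write_spectrum_csv(spec_, root / f)
        manifest["frozen_spectra"][lbl] = f
    (root / "truth.json").write_text(json.dumps(ds.truth, indent=2))
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root
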