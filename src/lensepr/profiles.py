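"""Transmembrane depth profiles of membrane physical properties.

Spin labels with nitroxide moieties at known depths — T-PC and CSL in the
polar headgroup region, n-PC and 9-SASL along the acyl chain, ASL at the
membrane center — turn pointwise EPR observables into profiles across one
bilayer leaflet.  Depth is ordinal (label-based): absolute nm placement
would need membrane-thickness data outside this package's scope, and the
analyses only need the ordering.

Provided here: profile assembly and validation, leaflet symmetrization
(mirroring one leaflet about the bilayer center), location of the largest
adjacent-depth fold change (cholesterol famously steps the oxygen transport
parameter up ~3x between carbons C9 and C10), and cross-species tabulation
of selected depths against lifespan with per-depth trend slopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEPTH_ORDER",
    "DepthPosition",
    "ProfilePoint",
    "DepthProfile",
    "assemble_profile",
    "symmetrize",
    "detect_abrupt_change",
    "lifespan_table",
]

#: depth ordinal per label: headgroup = 0, acyl carbons at their number,
#: ASL at the membrane center below the deepest labelled carbon
DEPTH_ORDER: Mapping[str, int] = {
    "T-PC": 0,
    "CSL": 0,
    "5-PC": 5,
    "7-PC": 7,
    "9-SASL": 9,
    "10-PC": 10,
    "12-PC": 12,
    "14-PC": 14,
    "16-PC": 16,
    "ASL-center": 17,
}

PROPERTIES = ("order_parameter", "T1_inv", "OTP", "two_Az")
CONDITIONS = ("no_chol", "saturated", "oversaturated")


@dataclass(frozen=True)
class DepthPosition:
    label: str

    def __post_init__(self) -> None:
        if self.label not in DEPTH_ORDER:
            raise ValueError(f"unknown depth label {self.label!r}")

    @property
    def depth_index(self) -> int:
        return DEPTH_ORDER[self.label]


@dataclass(frozen=True)
class ProfilePoint:
    position: DepthPosition
    value: float
    se: float = 0.0


@dataclass(frozen=True)
class DepthProfile:
    """Ordered (depth, value +/- se) series for one property and condition."""

    property: str
    condition: str
    species_label: str
    points: tuple[ProfilePoint, ...]

    def __post_init__(self) -> None:
        if self.property not in PROPERTIES:
            raise ValueError(f"unknown property {self.property!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        labels = [p.position.label for p in self.points]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate depth labels in profile")
        idx = [p.position.depth_index for p in self.points]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("profile points must be sorted by depth")
        if not all(np.isfinite(p.value) for p in self.points):
            raise ValueError("profile values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [p.position.label for p in self.points],
                "depth_index": [p.position.depth_index for p in self.points],
                "value": [p.value for p in self.points],
                "se": [p.se for p in self.points],
            }
        )


def assemble_profile(
    measurements: Sequence[tuple[str, float, float]],
    property: str,
    condition: str,
    species_label: str = "",
) -> DepthProfile:
    """Collect (label, value, se) triples into a validated, sorted profile."""
    if len(measurements) < 2:
        raise ValueError("need at least 2 depth points")
    pts = [
        ProfilePoint(DepthPosition(lbl), float(v), float(se))
        for lbl, v, se in measurements
    ]
    pts.sort(key=lambda p: (p.position.depth_index, p.position.label))
    return DepthProfile(
        property=property,
        condition=condition,
        species_label=species_label,
        points=tuple(pts),
    )


def symmetrize(profile: DepthProfile) -> pd.DataFrame:
    """Mirror a single-leaflet profile about the bilayer center.

    The deepest point sits on the mirror plane and is not duplicated, so a
    profile of n points becomes 2n - 1.  Mirrored points get depth index
    ``2*center - depth_index`` and a ``leaflet`` column; values and errors
    are copied unchanged.
    """
    df = profile.to_frame()
    center = df["depth_index"].max()
    mirror = df[df["depth_index"] < center].copy()
    mirror["depth_index"] = 2 * center - mirror["depth_index"]
    df["leaflet"] = "first"
    mirror["leaflet"] = "second"
    out = pd.concat([df, mirror.iloc[::-1]], ignore_index=True)
    return out.sort_values("depth_index", kind="stable").reset_index(drop=True)


def detect_abrupt_change(
    profile: DepthProfile,
) -> tuple[tuple[str, str], float]:
    """Largest adjacent-depth fold change in a profile.

    Points sharing a depth index (headgroup T-PC/CSL) are averaged first.
    Returns the (shallower, deeper) label pair with the maximum ratio
    ``value[deeper] / value[shallower]`` and that fold change.  Reported
    descriptively — the caller decides what counts as "abrupt".
    """
    df = profile.to_frame()
    if len(df) < 3:
        raise ValueError("need at least 3 depth points")
    if (df["value"] <= 0).any():
        raise ValueError("fold changes need strictly positive values")
    grouped = (
        df.groupby("depth_index", sort=True)
        .agg(label=("label", "/".join), value=("value", "mean"))
        .reset_index()
    )
    vals = grouped["value"].to_numpy()
    ratios = vals[1:] / vals[:-1]
    i = int(np.argmax(ratios))
    return (
        (grouped["label"].iloc[i], grouped["label"].iloc[i + 1]),
        float(ratios[i]),
    )


#: depths the cross-species comparison tabulates: headgroup, C5, center
COMPARISON_DEPTHS = ("T-PC", "CSL", "5-PC", "16-PC")


def lifespan_table(
    profiles: Sequence[DepthProfile],
    lifespans: Mapping[str, float],
    depths: Sequence[str] = COMPARISON_DEPTHS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate selected-depth values against species lifespan.

    Returns ``(table, slopes)``: a long-format table (species, lifespan,
    condition, property, depth label, value, se) and per (property,
    condition, depth) least-squares slopes of value vs lifespan with
    standard errors.  With fewer than 2 species a slope cannot be formed
    and comes back as NaN.
    """
    rows = []
    for prof in profiles:
        if prof.species_label not in lifespans:
            raise ValueError(f"no lifespan for species {prof.species_label!r}")
        for p in prof.points:
            if p.position.label in depths:
                rows.append(
                    {
                        "species": prof.species_label,
                        "lifespan_years": lifespans[prof.species_label],
                        "property": prof.property,
                        "condition": prof.condition,
                        "label": p.position.label,
                        "value": p.value,
                        "se": p.se,
                    }
                )
    if not rows:
        raise ValueError("no points at the requested depths")
    table = pd.DataFrame(rows)

    slope_rows = []
    for (prop, cond, lbl), grp in table.groupby(
        ["property", "condition", "label"]
    ):
        if grp["species"].nunique() < 2:
            slope, se = np.nan, np.nan
        else:
            fit = stats.linregress(grp["lifespan_years"], grp["value"])
            slope, se = fit.slope, fit.stderr
        slope_rows.append(
            {
                "property": prop,
                "condition": cond,
                "label": lbl,
                "slope_per_year": slope,
                "slope_se": se,
                "n_species": grp["species"].nunique(),
            }
        )
    return table, pd.DataFrame(slope_rows)
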