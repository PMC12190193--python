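#!/usr/bin/env python
"""Generate the synthetic species scenarios and write them to disk.

Produces the full mouse/pig/human x no-Chol/saturated/oversaturated grid of
datasets (air/N2 saturation-recovery decay pairs at ten depth labels, fluid
and frozen CW spectra, composition presets, ground-truth sidecars) under
scratch/scenarios/.  Downstream analysis scripts regenerate data from the
same seeds, so this script's on-disk output is a browsable artifact, not a
pipeline dependency.
"""

from pathlib import Path

from lensepr.synth import ScenarioSpec, make_species_scenario, write_scenario

OUT = Path(__file__).resolve().parent.parent / "scratch" / "scenarios"
BASE_SEED = 20240901

if __name__ == "__main__":
    n = 0
    for i, species in enumerate(("mouse", "pig", "human")):
        for j, condition in enumerate(("no_chol", "saturated", "oversaturated")):
            spec = ScenarioSpec(species, condition, seed=BASE_SEED + 10 * i + j)
            root = write_scenario(make_species_scenario(spec), OUT)
            n += 1
            print(f"wrote {root}")
    print(f"{n} scenarios under {OUT}")
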