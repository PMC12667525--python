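"""Simulate the demonstration anti-fibrotic drug screen.

Renders a synthetic 10-treatment organoid screen (normal control, TGFβ
stimulus, and TGFβ plus eight drugs spanning effective, partially
effective, ineffective and toxic profiles) over three imaging days and
three batches. Image stacks go to scratch/screen (binary, regenerable);
the construction ground truth goes to results/.
"""

from pathlib import Path

import pandas as pd

from fibroscreen.io import write_stack
from fibroscreen.synthetic import OrganoidSpec, ScreenDesign, Treatment, iter_screen

ROOT = Path(__file__).resolve().parents[1]
IMG_DIR = ROOT / "scratch" / "screen"
RESULTS = ROOT / "results"

# fibrosis_effect scales expected collagen-reporter signal; toxicity_effect
# is the fractional loss of nuclei. Profiles emulate a screen where TGFβ
# drives fibrosis, several inhibitors block it at varying potency, one
# compound is ineffective and one is overtly toxic.
TREATMENTS = [
    Treatment("NC", 0.30, 0.00),
    Treatment("TGFB", 2.50, 0.00),
    Treatment("TGFB+TGFBR1i", 0.35, 0.05),
    Treatment("TGFB+GSK3Bi", 0.50, 0.10),
    Treatment("TGFB+p38i", 0.45, 0.05),
    Treatment("TGFB+HDACi", 0.60, 0.10),
    Treatment("TGFB+BRD4i", 1.20, 0.10),
    Treatment("TGFB+DNMT1i", 2.20, 0.50),
    Treatment("TGFB+EZH2i", 2.40, 0.10),
    Treatment("TGFB+PPARGi", 2.00, 0.15),
]

DESIGN = ScreenDesign(
    treatments=TREATMENTS,
    days=[17, 21, 25],
    n_batches=3,
    organoids_per_batch_per_treatment=4,
    base_spec=OrganoidSpec(
        image_shape=(10, 192, 192), organoid_radius_px=70.0, n_nuclei_mean=60.0,
    ),
    seed=2026,
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for stack, truth in iter_screen(DESIGN):
        write_stack(stack, IMG_DIR)
        rows.append(truth.__dict__)
    truth = pd.DataFrame(rows)
    truth.to_csv(RESULTS / "screen_ground_truth.tsv", sep="\t", index=False,
                 float_format="%.10g")
    print(f"simulated {len(truth)} organoids "
          f"({len(TREATMENTS)} treatments x {len(DESIGN.days)} days x "
          f"{DESIGN.n_batches} batches x {DESIGN.organoids_per_batch_per_treatment})")
    print(f"stacks -> {IMG_DIR}")
    print(f"ground truth -> {RESULTS / 'screen_ground_truth.tsv'}")


if __name__ == "__main__":
    main()
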