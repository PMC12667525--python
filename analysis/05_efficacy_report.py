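"""Control-normalized fibrosis/cell-number time courses and statistics.

Normalizes per-organoid fibrosis intensity and nuclei count to the NC
mean at each day, runs Welch/Benjamini-Hochberg comparisons of every
treatment vs NC per day, and flags toxic treatments (significant cell
loss below the 0.7 threshold).
"""

from pathlib import Path

from fibroscreen.efficacy import compare_treatments, normalize_to_control, toxicity_flag
from fibroscreen.features import FeatureMatrix
from fibroscreen.plotting import plot_timecourse

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIGS = ROOT / "scratch" / "figures"


def main() -> None:
    matrix = FeatureMatrix.from_tsv(RESULTS / "features.tsv")
    points = normalize_to_control(matrix, "NC")
    points.to_csv(RESULTS / "timecourse.tsv", sep="\t", index=False,
                  float_format="%.10g")

    comparisons = compare_treatments(points, "NC")
    comparisons.to_csv(RESULTS / "comparisons.tsv", sep="\t", index=False,
                       float_format="%.10g")
    toxicity = toxicity_flag(points, "NC", threshold=0.7)
    toxicity.to_csv(RESULTS / "toxicity.tsv", sep="\t", index=False,
                    float_format="%.10g")

    print("fibrosis fold change vs NC (per day, Welch + BH):")
    for _, row in comparisons.sort_values(["day", "treatment"]).iterrows():
        print(f"  day {row['day']}: {row['treatment']:16s} "
              f"effect={row['effect']:5.2f}x  adj_p={row['adjusted_p']:.2e} "
              f"{row['significance_tier']}")

    toxic = toxicity[toxicity["toxic"]]
    print("\ntoxicity flags (mean normalized cell number < 0.7, adj p < 0.05):")
    if toxic.empty:
        print("  none")
    for _, row in toxic.iterrows():
        print(f"  day {row['day']}: {row['treatment']} "
              f"(cellnum {row['mean_cellnum_norm']:.2f}x NC)")

    FIGS.mkdir(parents=True, exist_ok=True)
    plot_timecourse(points, FIGS / "fibrosis_timecourse.png", "fibrosis_norm")
    plot_timecourse(points, FIGS / "cellnum_timecourse.png", "cellnum_norm")
    print(f"\ntables -> {RESULTS}, figures -> {FIGS}")


if __name__ == "__main__":
    main()
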