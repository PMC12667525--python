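"""Treatment-similarity profiling from mean feature vectors.

Z-scores the feature matrix, keeps features with high between-treatment
variance, averages z-scores per treatment and correlates treatments
(Pearson). The clustered heatmap is the screen's drug-similarity map:
effective anti-fibrotics should correlate with the untreated control,
ineffective ones with the TGFβ stimulus.
"""

from pathlib import Path

from fibroscreen.features import FeatureMatrix, select_features, zscore
from fibroscreen.plotting import plot_similarity_heatmap
from fibroscreen.profiling import pearson_similarity, treatment_profiles

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIGS = ROOT / "scratch" / "figures"


def main() -> None:
    matrix = FeatureMatrix.from_tsv(RESULTS / "features.tsv")
    scaled = select_features(zscore(matrix), variance_quantile=0.25)
    scaled.to_tsv(RESULTS / "features_scaled.tsv")
    print(f"selected {len(scaled.selected_features)}/18 features:")
    for name in scaled.selected_features:
        print(f"  {name}")

    sim = pearson_similarity(treatment_profiles(scaled))
    sim.r.to_csv(RESULTS / "similarity_mean_features.tsv", sep="\t",
                 float_format="%.10g")
    FIGS.mkdir(parents=True, exist_ok=True)
    plot_similarity_heatmap(
        sim, FIGS / "similarity_mean_features.png", "Mean-feature similarity"
    )

    nc_corr = sim.r["NC"].drop("NC").sort_values(ascending=False)
    print("\ncorrelation with NC (most control-like first):")
    for label, r in nc_corr.items():
        print(f"  {label:16s} r = {r:+.2f}")
    print(f"\nheatmap leaf order: {', '.join(sim.ordering)}")


if __name__ == "__main__":
    main()
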