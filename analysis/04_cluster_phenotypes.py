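"""Phenotypic k-means clustering and composition-based similarity.

Clusters all organoids in z-scored feature space (k chosen by mean
silhouette), tabulates the percentage of each treatment's organoids per
cluster, and correlates treatments on those composition rows — the
complementary similarity view to the mean-feature heatmap.
"""

from pathlib import Path

from fibroscreen.features import FeatureMatrix, select_features, zscore
from fibroscreen.plotting import plot_similarity_heatmap
from fibroscreen.profiling import cluster_composition, composition_similarity, fit_kmeans

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIGS = ROOT / "scratch" / "figures"


def main() -> None:
    matrix = FeatureMatrix.from_tsv(RESULTS / "features.tsv")
    scaled = select_features(zscore(matrix), variance_quantile=0.25)

    model = fit_kmeans(scaled, k="auto", seed=0)
    print("k selection diagnostics (mean silhouette):")
    for _, row in model.k_diagnostics.iterrows():
        marker = " <- selected" if int(row["k"]) == model.k else ""
        print(f"  k={int(row['k']):2d}  silhouette={row['mean_silhouette']:.3f}"
              f"  inertia={row['inertia']:.0f}{marker}")

    composition = cluster_composition(model, scaled.labels)
    composition.to_csv(RESULTS / "cluster_composition.tsv", sep="\t",
                       float_format="%.10g")
    model.k_diagnostics.to_csv(RESULTS / "k_diagnostics.tsv", sep="\t",
                               index=False, float_format="%.10g")
    print("\ncluster composition (% of treatment's organoids per cluster):")
    print(composition.round(1).to_string())

    sim = composition_similarity(composition)
    sim.r.to_csv(RESULTS / "similarity_composition.tsv", sep="\t",
                 float_format="%.10g")
    FIGS.mkdir(parents=True, exist_ok=True)
    plot_similarity_heatmap(
        sim, FIGS / "similarity_composition.png", "Cluster-composition similarity"
    )
    print(f"\nheatmap leaf order: {', '.join(sim.ordering)}")


if __name__ == "__main__":
    main()
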