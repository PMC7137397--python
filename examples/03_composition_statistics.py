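"""Class totals, Ring Index, detection counts and clustering on the
packaged 51-strain Thermococcales composition table."""

from archaeolipid.io import load_table1_fixture
from archaeolipid.stats import class_totals_table, composition_tree, pca
from archaeolipid.traits import ancestral_composition, count_by_filter, round_to_ten

table = load_table1_fixture()
totals = class_totals_table(table.profiles())

print(f"strains                : {len(totals)}")
print(f"diether (DGD) range    : {totals.dgd.min():.1f}-{totals.dgd.max():.1f}% "
      f"(~{round_to_ten(totals.dgd.min())}-{round_to_ten(totals.dgd.max())}%)")

n_rare, _ = count_by_filter(
    table.states, {"any": ["GMGT-0", "GMGT-1", "GDGT-1", "GDGT-2", "GDGT-3", "GDGT-4"]}
)
print(f"strains with H-shaped or ring-bearing tetraethers: {n_rare}")

# most ring-rich profile
ri = totals.ri.dropna()
print(f"highest Ring Index     : {ri.max():.3f} ({ri.idxmax()})")

res = pca(totals[["dgd", "gdgt", "gmgt", "gtgt"]])
print("PCA variance explained :", " ".join(f"{v:.0%}" for v in res.explained_variance_ratio[:3]))

basal = [
    "Palaeococcus ferrophilus", "Thermococcus aggregans", "Thermococcus sp. DT4",
    "Pyrococcus furiosus", "Thermococcus atlanticus", "Thermococcus onnurineus",
    "Thermococcus marinus", "Thermococcus cleftensis",
]
est = ancestral_composition(totals, basal)
print(f"basal-lineage mean split: DGD {est['dgd_mean']:.1f}% / "
      f"tetraether {est['tetraether_mean']:.1f}%  (~{est['dgd_rounded']}/"
      f"{est['tetraether_rounded']})")

newick = composition_tree(totals[["dgd", "gdgt", "gmgt", "gtgt"]])
print(f"lipid clustering tree  : {len(newick)} chars of newick, e.g. {newick[:60]}...")
# The ~50/50 basal split is the estimated membrane composition of the last
# common ancestor of the order; the clustering tree can be compared with a
# reference phylogeny via stats.tree_congruence.
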