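"""Generate a synthetic 20-site mosaic landscape and inspect its composition.

The generator plants land-use-specific species pools plus a shared
generalist pool, draws negative-binomial visit counts, and produces
sentinel-plant reproduction causally linked to visitation and network
position.  The preset mimics the scale of a tropical-agroecosystem survey:
20 sites over four land uses, ~57 visits per site, a Diptera-dominated
community with syrphids carrying about half of all visits.
"""

from polliscape import build_matrix, generate_landscape, study_shaped_preset

table, plants, truth = generate_landscape(study_shaped_preset(seed=1))

sites = table.sites
print(f"sites: {len(sites)}  (by land use: {sites['land_use'].value_counts().to_dict()})")
visits = table.records.groupby("order_name")["visits"].sum().sort_values(ascending=False)
print("total visits by insect order:")
for order, v in visits.items():
    print(f"  {order:12s} {v:4d}")
syr = table.records.query("family_name == 'Syrphidae'")["visits"].sum()
print(f"syrphid share of all visits: {syr / visits.sum():.2f}")

matrix = build_matrix(table)
print(f"\nbipartite network: {matrix.n_rows} sites x {matrix.n_cols} species, "
      f"{matrix.n_links} links, {matrix.F:.0f} total visits")
print(f"plants scored: {len(plants)} across {len(sites)} sites")
print("\nEach row of the visitation table is one site-species pair; the "
      "network's marginal totals drive every downstream metric.")
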