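"""Node specialization (d') and node strength on a synthetic landscape.

d' near 0 marks a generalist site attracting species common across the
landscape; d' near 1 marks a site visited by species found nowhere else.
A species' strength sums the sites' dependencies on it, so strengths add
up to the number of sites and a single species can dominate the network.
"""

import pandas as pd

from polliscape import build_matrix, dprime_all, generate_landscape, node_strength, study_shaped_preset

table, _, _ = generate_landscape(study_shaped_preset(seed=1))
matrix = build_matrix(table)

site_d = pd.DataFrame(
    [(r.node_id, r.d_prime) for r in dprime_all(matrix, "lower")], columns=["site", "d_prime"]
).sort_values("d_prime", ascending=False)
print("most specialized sites (d'):")
print(site_d.head(4).to_string(index=False))

strengths = pd.DataFrame(
    [(r.node_id, r.strength) for r in node_strength(matrix, "higher")],
    columns=["species", "strength"],
).sort_values("strength", ascending=False)
print("\nstrongest flower-visitor nodes:")
print(strengths.head(4).to_string(index=False))
print(f"\nsum of species strengths = {strengths['strength'].sum():.2f} "
      f"(= number of sites, {matrix.n_rows}): each site's dependencies sum to one.")
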