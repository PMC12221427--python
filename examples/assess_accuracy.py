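"""Accuracy assessment: the bundled Munich validation sample and fresh sampling.

First the published 530-point confusion matrix of a Copernicus land-cover map
of Munich is pushed through the statistics (user/producer accuracy, overall
accuracy, Cohen's kappa).  Then a synthetic map is sampled by stratified
random sampling, labelled with the generator's ground truth, and assessed —
a self-consistency check that comes out perfect by construction.
"""

import urbanfuse as uf

cm = uf.munich_confusion_matrix()
rep = uf.compute_report(cm)
r = rep.rounded()
print(f"Munich sample: n={cm.n}, overall accuracy {r['overall_accuracy']}, "
      f"kappa {r['kappa']}")
print("user accuracy: ", {k: v for k, v in list(r["user_accuracy"].items())[:4]}, "...")
print("producer accuracy: ", {k: v for k, v in list(r["producer_accuracy"].items())[:4]}, "...")

# stratified sampling on a synthetic map, labelled from the oracle map itself
scene = uf.generate_city(uf.CityRecipe(n_rows=80, n_cols=80, seed=3))
per_class = uf.proportional_allocation(scene.expected, total=150, floor=3)
points = uf.stratified_sample(scene.expected, per_class, seed=11)
points.table["ref_class"] = points.table["map_class"]  # ground-truth labels
cm2 = uf.build_matrix(points, sorted(set(points.table.map_class)))
rep2 = uf.compute_report(cm2)
print(f"synthetic self-check: n={cm2.n} points over {len(cm2.labels)} classes, "
      f"overall accuracy {rep2.overall_accuracy:.2f}, kappa {rep2.kappa:.2f}")
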