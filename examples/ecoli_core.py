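"""Genome-scale-style run: coupling statistics of the E. coli core network.

Loads the SBML model bundled with cobrapy (95 reactions), runs flux
coupling analysis and the full double-knockout simulation, and prints the
summary statistics.  Takes about a minute on one CPU.
"""

import os
import time

import cobra  # used only to locate its bundled SBML file

import fluxko as fk

path = os.path.join(os.path.dirname(cobra.__file__), "data", "textbook.xml.gz")
net = fk.load_network(path)
print(f"model: {len(net.reactions)} reactions, {len(net.metabolites)} metabolites, "
      f"{len(net.genes)} genes")

t0 = time.time()
model = fk.ConeModel(net)
table, pool = fk.fca(model)
partition = fk.partial_classes(table)
records = fk.double_knockout_analysis(model, table=table, pool=pool)
elapsed = time.time() - t0

imp = fk.impact_stats(table, partition, records)
opt = fk.option_stats(table, partition, records)
print(f"unblocked reactions: {imp.n_unblocked}; coupling classes: {imp.n_classes}")
print(f"single-knockout impact: {imp.single_mean_classes:.2f} classes "
      f"({imp.single_mean_reactions:.2f} reactions)")
print(f"double-knockout additional impact: {imp.double_mean_additional_classes:.1f} "
      f"classes ({imp.double_mean_additional_reactions:.1f} reactions); "
      f"joint-effect ratio {imp.double_ratio_percent:.0f}%")
print(f"knockout options per target: single {opt.single_mean_options:.2f}, "
      f"double {opt.double_mean_options:.0f}")

bio = fk.biomass_blockers(table, partition, records, "R_Biomass_Ecoli_core")
print(f"biomass reaction class size {bio.class_size}; "
      f"blocked by {bio.single_blocking_classes} single classes "
      f"({bio.single_blocking_reactions} reactions) and "
      f"{bio.double_blocking_class_pairs} class pairs "
      f"({bio.double_blocking_reaction_pairs} reaction pairs)")
print(f"{model.lp_calls} LPs in {elapsed:.0f}s")
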