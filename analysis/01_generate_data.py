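#!/usr/bin/env python
"""Generate the synthetic study bundle every downstream stage consumes.

Emulates the lineage-tracing design: WT and Brca1;Trp53 clone tables at
14/64/120/225 days (the mutant with a loss probability below the homeostatic
value, i.e. resistance to loss during side-branch regression), a random
ductal tree, and CSR vs clustered proliferation point patterns.

Writes results/data/{clones.tsv, tree.tsv, pattern_csr.tsv,
pattern_clustered.tsv, manifest.json}.
"""

import json
from dataclasses import asdict
from pathlib import Path

from ductclones.io import CloneTable, write_clone_table, write_ductal_tree, write_point_pattern
from ductclones.minimal import MinimalModelParams
from ductclones.synth import (
    LabellingDesign,
    PatternDesign,
    generate_clone_table,
    generate_ductal_tree,
    generate_point_pattern,
    per_color_density,
    units_per_labelled_cell,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = LabellingDesign(n_mice=6, glands_per_mouse=3, clones_per_gland_at_induction=150)
    wt_params = MinimalModelParams()
    mut_params = MinimalModelParams(homeostasis=False, loss_prob=0.45)

    print(f"labelling: 1 recombined cell per {design.recombined_per_cells}, "
          f"{design.n_colors} colours -> 1 per {per_color_density(design)} per colour, "
          f"{units_per_labelled_cell(design):.0f} units per labelled cell")

    wt = generate_clone_table(design, wt_params, seed=SEED)
    mut = generate_clone_table(design, mut_params, seed=SEED + 1, genotype="BRCA1_TRP53")
    table = CloneTable(records=wt.records + mut.records, provenance=wt.provenance)
    write_clone_table(table, OUT / "clones.tsv")
    print(f"clone table: {len(wt)} WT + {len(mut)} mutant surviving clones -> clones.tsv")

    tree = generate_ductal_tree(n_levels=7, branch_prob=0.6, slots_per_segment=40, seed=SEED)
    write_ductal_tree(tree, OUT / "tree.tsv")
    print(f"ductal tree: {len(tree.segments)} segments -> tree.tsv")

    csr = generate_point_pattern(PatternDesign(mode="csr"), seed=SEED)
    clustered = generate_point_pattern(PatternDesign(mode="clustered"), seed=SEED)
    write_point_pattern(csr, OUT / "pattern_csr.tsv")
    write_point_pattern(clustered, OUT / "pattern_clustered.tsv")
    print(f"point patterns: {csr.n_points} CSR and {clustered.n_points} clustered points")

    manifest = {
        "seed": SEED,
        "design": asdict(design),
        "wt_params": asdict(wt_params),
        "mut_params": asdict(mut_params),
        "tree": {"n_levels": 7, "branch_prob": 0.6, "slots_per_segment": 40},
        "patterns": {"csr": asdict(PatternDesign(mode="csr")),
                     "clustered": asdict(PatternDesign(mode="clustered"))},
    }
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print("manifest.json written")


if __name__ == "__main__":
    main()
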