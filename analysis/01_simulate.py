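"""Generate the planted expression compendium standing in for the microarray data.

The stated world: 2000 genes, 30 conditions × 3 replicates across 2 projects,
20 sparse modules of 50 genes (modules 0/1 overlap by 10 genes), condition-
level activities of sd 20, measurement noise sd 0.1, and +20 activations of
modules 2–4 in the last two conditions. The ground-truth TRN carries one
regulator per module plus three deliberately mismatched regulons (superset,
partial, decoy) so every overlap category occurs downstream.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from modulome import generate_compendium
from modulome.compendium import write_expression, write_metadata

import common


def main() -> None:
    common.ensure_dirs()
    compendium, truth = generate_compendium(seed=common.GENERATOR_SEED)
    write_expression(compendium, common.EXPR)
    write_metadata(compendium, common.META)
    truth.trn_true.to_csv(common.TRN)
    truth.to_json(common.TRUTH)

    n_edges = len(truth.trn_true.edges)
    n_regs = truth.trn_true.edges.regulator.nunique()
    print(f"compendium: {compendium.values.shape[0]} genes x "
          f"{compendium.values.shape[1]} samples "
          f"({compendium.metadata.condition_id.nunique()} conditions, "
          f"{compendium.metadata.project_id.nunique()} projects)")
    print(f"planted modules: {len(truth.module_ids)}; "
          f"ground-truth TRN: {n_edges} edges, {n_regs} regulators")
    print(f"planted activations: {sorted(set(m for m, _ in truth.planted_shifts))} "
          f"in {sorted(set(c for _, c in truth.planted_shifts))}")
    print(f"wrote {common.EXPR}, {common.META}, {common.TRN}, {common.TRUTH}")


if __name__ == "__main__":
    main()
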