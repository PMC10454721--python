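"""Quality-control replicates and center the compendium to reference conditions.

Samples whose best within-replicate-group Pearson correlation falls below
0.95 are removed; the survivors are normalized by subtracting, per project,
the mean expression of the project's reference condition, turning values into
log2 fold changes against the control state.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from modulome import (
    center_to_reference,
    filter_replicates,
    load_expression,
    replicate_correlation_summary,
)
from modulome.compendium import write_expression, write_metadata

import common


def main() -> None:
    common.ensure_dirs()
    compendium = load_expression(common.EXPR, common.META)
    summary = replicate_correlation_summary(compendium)
    filtered, removed = filter_replicates(compendium, min_corr=0.95)
    centered = center_to_reference(filtered)

    write_expression(filtered, common.FILTERED)
    write_expression(centered, common.CENTERED)
    write_metadata(filtered, common.META)  # metadata of surviving samples
    with open(common.RESULTS / "qc_summary.json", "w") as fh:
        json.dump(
            {
                "median_replicate_correlation": summary["median"],
                "min_replicate_correlation": summary["min"],
                "n_replicate_pairs": summary["n_pairs"],
                "removed_samples": removed,
            },
            fh,
            indent=1,
        )

    print(f"replicate correlation: median {summary['median']:.3f}, "
          f"min {summary['min']:.3f} over {summary['n_pairs']} pairs")
    print(f"samples removed by the 0.95 filter: {len(removed)} {removed}")
    print(f"centered matrix written to {common.CENTERED}")


if __name__ == "__main__":
    main()
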