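"""Compare iModulon gene sets with the draft-TRN regulons.

One-sided hypergeometric enrichment over the expression-matrix gene universe
with global BH correction; overlaps are summarized by regulon recall / iModulon
recall and binned into the four categories at the 0.6 threshold.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from modulome import define_imodulons, enrich_regulons
from modulome.enrichment import RegulonTable

import common
importer = __import__("importlib").import_module
define_mod = importer("04_define_imodulons")


def main() -> None:
    common.ensure_dirs()
    d, X = define_mod.load_decomposition()
    ims = define_imodulons(d, X=X)
    trn = RegulonTable.from_csv(common.TRN)
    result = enrich_regulons(ims, trn, universe=set(X.index))
    result.to_csv(common.RESULTS / "enrichment.csv", index=False)

    best = result[result.is_best & (result.fdr < 0.05)]
    counts = best.category.value_counts().to_dict()
    print(f"iModulon x regulon pairs tested: {len(result)}")
    print(f"iModulons with a significant best match (FDR < 0.05): {len(best)}")
    print(f"best-match categories: {counts}")
    print(best[["imodulon", "regulator", "shared", "rr", "mr", "category"]]
          .sort_values("imodulon").to_string(index=False))


if __name__ == "__main__":
    main()
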