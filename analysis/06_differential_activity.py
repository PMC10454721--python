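"""Differential iModulon activity: target conditions versus the references.

An iModulon is called significantly different when the absolute difference of
group-mean activities exceeds 5 AND the Welch-t BH FDR is below 0.05; a
per-condition stage profile of mean activities is also written.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from modulome import define_imodulons, diff_activity, stage_activity_profile
from modulome.compendium import read_metadata

import common
importer = __import__("importlib").import_module
define_mod = importer("04_define_imodulons")


def main() -> None:
    common.ensure_dirs()
    d, X = define_mod.load_decomposition()
    ims = define_imodulons(d, X=X)
    A = d.A.copy()
    A.index = [im.name for im in ims]
    meta = read_metadata(common.META)

    ref = meta.index[meta.condition_id.isin(common.REFERENCE_CONDITIONS)].tolist()
    tgt = meta.index[meta.condition_id.isin(common.TARGET_CONDITIONS)].tolist()
    res = diff_activity(A, ref, tgt, activity_threshold=5.0, fdr_level=0.05)
    res.to_csv(common.RESULTS / "diff_activity.csv")

    order = sorted(meta.condition_id.unique())
    profile = stage_activity_profile(A, meta, order)
    profile.round(4).to_csv(common.RESULTS / "stage_activity_profile.csv")

    sig = res[res.significant]
    n_up = int((sig.direction == "up").sum())
    n_down = int((sig.direction == "down").sum())
    print(f"significantly different iModulons (|diff| > 5, FDR < 0.05): "
          f"{len(sig)} ({n_up} up, {n_down} down)")
    print(sig[["mean_diff", "fdr", "direction"]].round(4).to_string())


if __name__ == "__main__":
    main()
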