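"""Synthetic expression compendia with planted modules and a ground-truth TRN.

The generator emulates the statistical structure the decomposition assumes:
log2-scale values, conditions with a few replicates apiece (replicates share
the same true activity column; only measurement noise differs, so replicate
correlations are high), per-project reference conditions, k sparse gene-weight
source modules with condition-dependent activities, additive Gaussian noise,
and a planted TRN whose regulons align with the planted modules (one regulator
per module, targets = module genes).

Member weights are drawn as sign · (0.5 + Exp(1)) — a shifted-Laplace
magnitude — so the sources are heavy-tailed (ICA-identifiable) and every
planted member carries a non-negligible weight. Conditions named in
`planted_shifts` copy their project reference's baseline activity before the
shift is added, so a planted activation is the ONLY systematic difference
between the target and reference states, exactly the contrast the
differential-activity and active-TRN stages are meant to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compendium import ExpressionCompendium
from .enrichment import RegulonTable
from .imodulons import IModulon

DEFAULT_SHIFT = 20.0


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated compendium."""

    M_true: pd.DataFrame  # genes × modules, unit-norm columns
    A_true: pd.DataFrame  # modules × samples
    module_members: dict[str, set[str]]
    trn_true: RegulonTable
    core_regulators: dict[str, str]  # module id -> its one-regulator name
    planted_shifts: dict[tuple[str, str], float]  # (module, condition) -> delta
    noise_sd: float
    seed: int

    @property
    def module_ids(self) -> list[str]:
        return list(self.M_true.columns)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "module_members": {m: sorted(g) for m, g in self.module_members.items()},
            "core_regulators": self.core_regulators,
            "planted_shifts": [
                {"module": m, "condition": c, "delta": d}
                for (m, c), d in sorted(self.planted_shifts.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def generate_compendium(
    n_genes: int = 2000,
    n_conditions: int = 30,
    replicates_per_condition: int = 3,
    k_modules: int = 20,
    genes_per_module: int = 50,
    activity_base_sd: float = 20.0,
    planted_shifts: dict[tuple[int, int], float] | None = None,
    noise_sd: float = 0.1,
    n_projects: int = 2,
    seed: int = 0,
    module_overlap: int = 10,
    plant_category_mismatches: bool = True,
) -> tuple[ExpressionCompendium, SyntheticTruth]:
    """Generate an (uncentered) log2 compendium plus its ground truth.

    Parameters
    ----------
    planted_shifts
        Map from (module index, condition index) to an activity delta. The
        default plants a +20 shift for modules 2–4 in the last two conditions
        (2 conditions × 3 replicates = 6 target samples). Shifted conditions
        inherit their project reference's baseline activities, see module
        docstring. Reference conditions themselves cannot be shifted.
    module_overlap
        Number of genes module 1 shares with module 0 (planted overlap so
        membership recovery is exercised on non-disjoint modules).
    plant_category_mismatches
        Plant three extra regulons (a superset, a partial regulon, and a
        decoy) so the four RR/MR overlap categories all occur.
    """
    if k_modules > n_conditions * replicates_per_condition:
        raise ValueError("k_modules must not exceed the number of samples")
    if k_modules * genes_per_module > n_genes:
        raise ValueError("module membership exceeds the gene universe")
    if n_projects < 1 or n_projects > n_conditions:
        raise ValueError("need 1 <= n_projects <= n_conditions")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    module_ids = [f"mod_{m:02d}" for m in range(k_modules)]
    conditions = [f"cond_{i:02d}" for i in range(n_conditions)]

    # -- membership and sparse weights -------------------------------------
    perm = rng.permutation(n_genes)
    members: dict[str, set[str]] = {}
    member_idx: dict[str, np.ndarray] = {}
    for m, mid in enumerate(module_ids):
        idx = perm[m * genes_per_module : (m + 1) * genes_per_module]
        member_idx[mid] = idx
        members[mid] = {genes[i] for i in idx}
    if module_overlap > 0 and k_modules >= 2:
        shared = member_idx[module_ids[0]][-module_overlap:]
        member_idx[module_ids[1]] = np.concatenate([member_idx[module_ids[1]], shared])
        members[module_ids[1]] |= {genes[i] for i in shared}

    M = np.zeros((n_genes, k_modules))
    for m, mid in enumerate(module_ids):
        idx = member_idx[mid]
        mags = 0.5 + rng.exponential(1.0, size=idx.size)
        # every module gets one clear flagship gene so the sign-orientation
        # convention (largest-|weight| entry positive) is stable under
        # estimation error rather than decided by a near-tie
        mags[np.argmax(mags)] *= 1.5
        signs = rng.choice([-1.0, 1.0], size=idx.size)
        M[idx, m] = mags * signs
        M[:, m] /= np.linalg.norm(M[:, m])
        # canonical orientation (largest-|weight| gene positive), matching the
        # decomposition's sign convention so planted activity shifts keep
        # their sign through recovery
        if M[np.argmax(np.abs(M[:, m])), m] < 0:
            M[:, m] *= -1.0

    # -- metadata ----------------------------------------------------------
    project_of = {c: f"proj_{i % n_projects}" for i, c in enumerate(conditions)}
    reference_of = {f"proj_{p}": conditions[p] for p in range(n_projects)}
    sample_rows = []
    for cond in conditions:
        for r in range(replicates_per_condition):
            sample_rows.append(
                {
                    "sample_id": f"{cond}_r{r + 1}",
                    "project_id": project_of[cond],
                    "condition_id": cond,
                    "reference_condition_id": reference_of[project_of[cond]],
                    "replicate_group": cond,
                }
            )
    metadata = pd.DataFrame(sample_rows).set_index("sample_id")

    # -- activities --------------------------------------------------------
    if planted_shifts is None:
        planted_shifts = {
            (m, c): DEFAULT_SHIFT
            for m in (2, 3, 4)
            for c in (n_conditions - 2, n_conditions - 1)
            if k_modules > 4
        }
    shifts: dict[tuple[str, str], float] = {
        (module_ids[m], conditions[c]): float(delta)
        for (m, c), delta in planted_shifts.items()
    }
    shifted_conditions = {c for (_, c) in shifts}
    for c in shifted_conditions:
        if c in reference_of.values():
            raise ValueError(f"cannot plant a shift in reference condition {c!r}")

    A_cond = rng.normal(0.0, activity_base_sd, size=(k_modules, n_conditions))
    cond_index = {c: i for i, c in enumerate(conditions)}
    for c in shifted_conditions:
        ref = reference_of[project_of[c]]
        A_cond[:, cond_index[c]] = A_cond[:, cond_index[ref]]
    for (mid, c), delta in shifts.items():
        A_cond[module_ids.index(mid), cond_index[c]] += delta

    samples = list(metadata.index)
    A_samples = np.column_stack(
        [A_cond[:, cond_index[metadata.loc[s, "condition_id"]]] for s in samples]
    )

    # -- expression --------------------------------------------------------
    X = M @ A_samples + rng.normal(0.0, noise_sd, size=(n_genes, len(samples)))
    values = pd.DataFrame(X, index=genes, columns=samples)
    compendium = ExpressionCompendium(values, metadata, centered=False)

    # -- ground-truth TRN --------------------------------------------------
    core_regulators = {mid: f"Reg_{mid}" for mid in module_ids}
    edge_rows = [
        {"regulator": core_regulators[mid], "target_gene": g,
         "effect": "+", "evidence": "synthetic"}
        for mid in module_ids
        for g in sorted(members[mid])
    ]
    if plant_category_mismatches and k_modules >= 2:
        in_module = set().union(*members.values())
        pool = sorted(set(genes) - in_module)
        n_super = min(60, len(pool) // 3)
        n_decoy = min(30, len(pool) // 3)
        extra = rng.permutation(len(pool))
        super_targets = sorted(members[module_ids[0]]) + [pool[i] for i in extra[:n_super]]
        decoy_targets = [pool[i] for i in extra[n_super : n_super + n_decoy]]
        part_targets = sorted(members[module_ids[1]])[: max(5, genes_per_module // 3)]
        for reg, targets in (
            ("Reg_super", super_targets),
            ("Reg_part", part_targets),
            ("Reg_decoy", decoy_targets),
        ):
            edge_rows.extend(
                {"regulator": reg, "target_gene": g, "effect": "+", "evidence": "synthetic"}
                for g in targets
            )
    trn = RegulonTable(pd.DataFrame(edge_rows))

    truth = SyntheticTruth(
        M_true=pd.DataFrame(M, index=genes, columns=module_ids),
        A_true=pd.DataFrame(A_samples, index=module_ids, columns=samples),
        module_members=members,
        trn_true=trn,
        core_regulators=core_regulators,
        planted_shifts=shifts,
        noise_sd=noise_sd,
        seed=seed,
    )
    return compendium, truth


def score_recovery(imodulons: list[IModulon], truth: SyntheticTruth) -> pd.DataFrame:
    """Greedy one-to-one matching of iModulons to planted modules by Jaccard.

    Returns one row per planted module with its matched iModulon (or None)
    and the Jaccard index between the thresholded gene set and the planted
    membership.
    """
    modules = truth.module_ids
    cands = [im for im in imodulons if im.member_genes]
    jac = np.zeros((len(modules), len(cands)))
    for i, mid in enumerate(modules):
        planted = truth.module_members[mid]
        for j, im in enumerate(cands):
            inter = len(planted & im.member_genes)
            union = len(planted | im.member_genes)
            jac[i, j] = inter / union if union else 0.0

    matched: dict[int, tuple[int, float]] = {}
    work = jac.copy()
    while work.size and work.max() > 0:
        i, j = np.unravel_index(np.argmax(work), work.shape)
        matched[int(i)] = (int(j), float(work[i, j]))
        work[i, :] = -1.0
        work[:, j] = -1.0

    rows = []
    for i, mid in enumerate(modules):
        j, score = matched.get(i, (None, 0.0))
        rows.append(
            {
                "module": mid,
                "imodulon": cands[j].name if j is not None else None,
                "jaccard": score,
            }
        )
    return pd.DataFrame(rows)
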