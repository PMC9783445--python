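"""Phenogram (traitgram) coordinates, branch-wise character maps, group
summaries, and the end-to-end pipeline driver.

Coordinate computation is kept separate from any plotting so everything
runs headless; the exported tables carry all the numbers a phenogram or
violin plot needs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative import (
    match_species,
    nagelkerke_pseudo_r2,
    phylo_ancova,
    predict_body_mass,
    size_correct,
)
from .convergence import c1_significance, collapse_acquisitions, asr_bm
from .synthetic import (
    DEFAULT_N_SHIFTS,
    DEFAULT_N_TIPS,
    DEFAULT_ROOT_AGE,
    SUBTERRANEAN,
    TALPID_LIKE,
    TraitSimConfig,
    paint_regimes,
    simulate_traits,
    simulate_tree,
)
from .trees import FossilGraft, TimeTree, graft_fossil, read_tree

__all__ = [
    "phenogram",
    "branch_state_map",
    "group_summary",
    "run_pipeline",
    "build_synthetic_dataset",
]


def phenogram(
    tree: TimeTree, traits: dict[str, float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenogram layout: per-node (time from root, trait state) plus edges.

    Tip coordinates are (tip height, observed trait) — a fossil tip sits at
    its true pre-present time; internal states are BM ML reconstructions.
    Returns (nodes, edges) DataFrames; nodes are indexed by a stable
    preorder id.
    """
    states = asr_bm(tree, traits)
    depths = tree.depths()
    ids = {node: k for k, node in enumerate(tree.preorder())}
    rows = [
        {
            "node_id": ids[node],
            "name": node.name or "",
            "is_tip": node.is_leaf,
            "time": depths[node],
            "state": states[node],
        }
        for node in tree.preorder()
    ]
    edges = [
        {"parent_id": ids[node.parent], "child_id": ids[node]}
        for node in tree.preorder()
        if node.parent is not None
    ]
    return pd.DataFrame(rows), pd.DataFrame(edges)


def branch_state_map(
    tree: TimeTree, traits: dict[str, float], resolution: int = 10
) -> pd.DataFrame:
    """Linear interpolation of ML states along each edge.

    ``resolution`` points per edge (endpoints included); used for
    continuous-character maps painted on the tree.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    states = asr_bm(tree, traits)
    depths = tree.depths()
    ids = {node: k for k, node in enumerate(tree.preorder())}
    rows = []
    frac = np.linspace(0.0, 1.0, resolution)
    for node in tree.preorder():
        if node.parent is None:
            continue
        s0, s1 = states[node.parent], states[node]
        t0, t1 = depths[node.parent], depths[node]
        for f, t, s in zip(frac, t0 + frac * (t1 - t0), s0 + frac * (s1 - s0)):
            rows.append(
                {
                    "parent_id": ids[node.parent],
                    "child_id": ids[node],
                    "fraction": f,
                    "time": t,
                    "state": s,
                }
            )
    return pd.DataFrame(rows)


def group_summary(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group n / mean / median / quartiles of a (size-corrected) trait."""
    df = pd.DataFrame({"value": values, "group": groups}).dropna()
    out = (
        df.groupby("group")["value"]
        .agg(
            n="count",
            mean="mean",
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    assert int(out["n"].sum()) == len(df)
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def build_synthetic_dataset(cfg: dict, seed: int):
    """Generate the synthetic study system described by a ``synth`` block.

    Returns (tree, trait table, clade_map).  The table mirrors the study's
    input format: lifestyle labels (with a fossorial-talpid flag), a bone
    volume fraction and a diaphyseal compactness trait (each an OU regime
    response plus an allometric body-size component), body mass, and
    humeral cross-sectional area tied to mass by a noisy power law.
    """
    n_tips = int(cfg.get("n_tips", DEFAULT_N_TIPS))
    n_shifts = int(cfg.get("n_shifts", DEFAULT_N_SHIFTS))
    root_age = float(cfg.get("root_age", DEFAULT_ROOT_AGE))
    sigma2 = float(cfg.get("sigma2", 0.02))
    alpha = float(cfg.get("alpha", np.log(2.0) / 25.0))
    mass_slope = float(cfg.get("mass_slope", 0.2))

    tree = simulate_tree(n_tips, seed=seed, fossil_tips=int(cfg.get("fossil_tips", 0)),
                         root_age=root_age)
    rtree = paint_regimes(tree, n_shifts, seed=seed + 1,
                          talpid_like=bool(cfg.get("talpid_like", True)))

    bvtv_cfg = TraitSimConfig(
        model="OU", sigma2=sigma2, alpha=alpha, seed=seed + 2,
        theta_by_regime={"background": 0.0, SUBTERRANEAN: 1.0, TALPID_LIKE: 2.0},
    )
    comp_cfg = TraitSimConfig(
        model="OU", sigma2=sigma2, alpha=alpha, seed=seed + 3,
        theta_by_regime={"background": 0.0, SUBTERRANEAN: 0.3, TALPID_LIKE: 0.3},
    )
    mass_cfg = TraitSimConfig(model="BM", sigma2=0.02, root_state=1.5, seed=seed + 4)

    bvtv_ou = simulate_traits(rtree, bvtv_cfg)
    comp_ou = simulate_traits(rtree, comp_cfg)
    log_mass = simulate_traits(rtree.tree, mass_cfg)

    rng = np.random.default_rng(seed + 5)
    names = tree.tip_names()
    lm = np.array([log_mass[s] for s in names])
    # humeral cross-sectional area from a mass ~ CSA^1.5 power law
    log_csa = (lm - 1.0) / 1.5 + rng.normal(0.0, 0.05, len(names))
    table = pd.DataFrame(
        {
            "lifestyle": [
                "subterranean"
                if rtree.regime_of_tip[s] in (SUBTERRANEAN, TALPID_LIKE)
                else "non_subterranean"
                for s in names
            ],
            "fossorial_talpid": [
                rtree.regime_of_tip[s] == TALPID_LIKE for s in names
            ],
            "bvtv": [bvtv_ou[s] + mass_slope * log_mass[s] for s in names],
            "compactness": [comp_ou[s] + mass_slope * log_mass[s] for s in names],
            "body_mass_g": 10.0**lm,
            "csa_mm2": 10.0**log_csa,
            "excluded": False,
        },
        index=pd.Index(names, name="species"),
    )
    return tree, table, rtree.acquisition_members()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def run_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis: tree variants -> body-mass imputation ->
    size correction -> phyloANCOVA per trait -> acquisition collapsing and
    the C1 convergence test (with and without excluded clades) -> group
    summaries.  Every analysis is repeated for each tree variant.

    The report bundle (CSV/JSON + run.log) is a pure function of
    (config, seed); reruns are byte-identical.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    n_sim = int(cfg.get("n_sim", 1000))
    out = Path(out_dir or cfg.get("out_dir", "osteophylo_out"))
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"osteophylo {__version__}", f"seed {seed}"]

    # --- inputs -----------------------------------------------------------
    if "synth" in cfg:
        base_tree, table, clade_map = build_synthetic_dataset(cfg["synth"], seed)
        log.append(
            f"synthetic dataset: {len(base_tree)} tips, "
            f"{len(clade_map)} acquisitions"
        )
    else:
        base_tree = read_tree(Path(cfg["tree"]).read_text())
        table = pd.read_csv(cfg["traits"], index_col=0)
        clade_map = dict(cfg.get("clade_map", {}))
        report = match_species(base_tree, table.index)
        log.append(
            f"species matching: {len(report['matched'])} matched, "
            f"{len(report['tree_only'])} tree-only, "
            f"{len(report['table_only'])} table-only"
        )

    trait_columns = list(cfg.get("trait_columns", ["bvtv", "compactness"]))
    group_column = cfg.get("group_column", "lifestyle")
    mass_column = cfg.get("mass_column", "body_mass_g")
    exclude = list(cfg.get("exclude", []))
    if "excluded" in table.columns:
        table = table[~table["excluded"].astype(bool)]

    # --- tree variants ----------------------------------------------------
    variants: dict[str, TimeTree] = {}
    for f in cfg.get("fossils", []):
        graft = FossilGraft(
            name=f["name"],
            age=float(f["age"]),
            spanning=tuple(f["spanning"]),
            rule=dict(f["rule"]),
            variant_label=f.get("variant", f["name"]),
        )
        variants[graft.variant_label] = graft_fossil(base_tree, graft)
    if not variants:
        variants["base"] = base_tree

    results: dict = {"variants": {}}
    for vname, tree in sorted(variants.items()):
        log.append(f"variant {vname}: {len(tree)} tips")
        vout = _run_variant(
            tree, table, clade_map, trait_columns, group_column, mass_column,
            exclude, n_sim, seed, vname, out, log,
        )
        results["variants"][vname] = vout

    # --- phenogram + summary (first variant, first trait) -----------------
    first = sorted(variants)[0]
    resid = results["variants"][first]["residuals"][trait_columns[0]]
    nodes, edges = phenogram(variants[first], resid.to_dict())
    nodes.to_csv(out / "phenogram.csv", index=False)

    grp = _three_way_groups(table)
    summary = group_summary(resid, grp.loc[resid.index])
    summary.to_csv(out / "summary.csv", index=False)
    log.append("wrote phenogram.csv, summary.csv")

    (out / "run.log").write_text("\n".join(log) + "\n")
    results["out_dir"] = out
    return results


def _three_way_groups(table: pd.DataFrame) -> pd.Series:
    grp = pd.Series("non_subterranean", index=table.index)
    if "lifestyle" in table.columns:
        grp[table["lifestyle"] == "subterranean"] = "other_subterranean"
    if "fossorial_talpid" in table.columns:
        grp[table["fossorial_talpid"].astype(bool)] = "fossorial_talpid"
    return grp


def _run_variant(
    tree, table, clade_map, trait_columns, group_column, mass_column,
    exclude, n_sim, seed, vname, out, log,
):
    species = [s for s in tree.tip_names() if s in table.index]
    tab = table.loc[species]

    # body mass: impute from CSA when available
    if "csa_mm2" in tab.columns and tab["csa_mm2"].notna().sum() >= 10:
        tab, mass_fit = predict_body_mass(tab, tree, mass_col=mass_column)
        mass = tab["body_mass_pred_g"].fillna(tab[mass_column])
        log.append(
            f"[{vname}] body-mass allometry: slope "
            f"{mass_fit.beta[1]:.4f}, pseudo-R2 {mass_fit.pseudo_r2:.4f}"
        )
    else:
        mass_fit = None
        mass = tab[mass_column]

    ancova_rows = []
    residuals: dict[str, pd.Series] = {}
    for trait in trait_columns:
        resid, _ = size_correct(tab[trait], mass, tree)
        residuals[trait] = resid
        fit = phylo_ancova(
            tab[trait], tab[group_column], tree,
            covariate=np.log10(mass.astype(float)),
        )
        null = phylo_ancova(
            tab[trait], tab[group_column], tree, covariate=None,
        )
        ancova_rows.append(
            {
                "trait": trait,
                "n": fit.n,
                "lambda": fit.lambda_hat,
                "group_F": fit.group_test["F"],
                "group_p": fit.group_test["p"],
                "covariate_coef": fit.beta[-1],
                "covariate_p": fit.pvalue[-1],
                "loglik": fit.loglik,
            }
        )
        log.append(
            f"[{vname}] phyloANCOVA {trait}: group p = "
            f"{fit.group_test['p']:.3e}, lambda = {fit.lambda_hat:.3f}"
        )
    pd.DataFrame(ancova_rows).to_csv(out / f"ancova_{vname}.csv", index=False)

    # convergence on the acquisition-collapsed tree
    c1_block: dict = {}
    if clade_map:
        for trait in trait_columns:
            resid = residuals[trait]
            cmap = {
                k: [m for m in v if m in resid.index]
                for k, v in clade_map.items()
            }
            cmap = {k: v for k, v in cmap.items() if v}
            ct = collapse_acquisitions(tree, cmap, resid.to_dict())
            focal = ct.acquisition_tips
            res_all = c1_significance(ct, focal, n_sim=n_sim, seed=seed)
            entry = {
                "all": _c1_json(res_all),
                "n_acquisitions": len(focal),
            }
            kept = [f for f in focal if f not in exclude]
            if len(kept) >= 2 and len(kept) < len(focal):
                res_ex = c1_significance(ct, kept, n_sim=n_sim, seed=seed)
                entry["excluding"] = _c1_json(res_ex)
                entry["excluded"] = sorted(set(focal) - set(kept))
                entry["n_acquisitions_excluding"] = len(kept)
            c1_block[trait] = entry
            log.append(
                f"[{vname}] C1 {trait}: {res_all.c1:.4f} "
                f"(p = {res_all.p_value:.4f}, {len(focal)} acquisitions)"
            )
        (out / f"c1_{vname}.json").write_text(
            json.dumps(c1_block, indent=2, sort_keys=True) + "\n"
        )
        pairs = []
        for trait, entry in c1_block.items():
            for ti, tj, dtip, dmax in entry["all"]["per_pair"]:
                pairs.append(
                    {"trait": trait, "tip_i": ti, "tip_j": tj,
                     "dtip": dtip, "dmax": dmax}
                )
        pd.DataFrame(pairs).to_csv(out / f"c1_pairs_{vname}.csv", index=False)

    return {
        "ancova": pd.DataFrame(ancova_rows),
        "c1": c1_block,
        "residuals": residuals,
        "mass_fit": mass_fit,
    }


def _c1_json(res) -> dict:
    return {
        "c1": res.c1,
        "p_value": res.p_value,
        "n_sim": res.n_sim,
        "n_dropped": res.n_dropped,
        "sigma2_used": res.sigma2_used,
        "seed": res.seed,
        "focal_tips": res.focal_tips,
        "per_pair": [list(p) for p in res.per_pair],
    }
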