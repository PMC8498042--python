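"""End-to-end in-silico reciprocal recurrent genomic selection experiment.

One cycle of the female-pool RRGS scheme: train an additive + dominance
ridge-BLUP model on a factorial of founder hybrids, select founder females
on predicted GCA, recombine them in a round robin, genomically select F2
plants within families, advance by single-seed descent to F5, select again
among visually preselected F5:6 lines (with a random-drawn control branch),
produce testcross hybrids, evaluate them in a multi-location trial with a
drought-stressed environment subset, and run the downstream analyses:
BLUEs, group contrasts, heterosis, observed vs expected response, realized
prediction ability and genotype-by-environment diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gxe as gxe_mod
from . import pheno, popgen, selection
from .prediction import expected_hybrid_matrix, fit_rrblup_ad
from .types import GenotypeMatrix, TrialDesign

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_rrgs_experiment",
    "realized_prediction_ability",
    "group_contrasts",
]


@dataclass
class ExperimentConfig:
    """Settings of the simulated breeding program.

    Defaults mirror the reference program: 120 x 15 founders, 20 C0
    females recombined in a round robin, 629 F2 plants with 3 selected per
    family, advance to F5, 382 visually preselected F5:6 lines of which 50
    are selected (C1S) next to 30 random controls (C1R), 3 testers, and a
    6-location evaluation with 2 drought-stressed sites. Smaller studies
    should scale the counts jointly.
    """

    # founders and genome
    n_females: int = 120
    n_males: int = 15
    n_markers: int = 4031
    n_chromosomes: int = 21
    chrom_length_cm: float = 150.0
    maf_low: float = 0.05
    maf_high: float = 0.5
    # trait architecture
    n_qtl: int = 300
    var_additive: float = 7.0
    dominance_ratio: float = 0.6
    intercept: float = 90.0
    # training design
    factorial_fraction: float = 0.9
    n_training_envs: int = 6
    var_train_gxe: float = 2.0
    var_train_residual: float = 5.7
    rrblup_varcomp: tuple | str = "reml"
    # selection scheme
    n_c0: int = 20
    f2_total: int = 629
    f2_select_per_family: int = 3
    ssd_generations: int = 3
    f5_per_f2: int = 8
    n_visual: int = 382
    visual_aux_correlation: float = 0.2
    n_c1s: int = 50
    n_c1r: int = 30
    n_testers: int = 3
    n_checks: int = 7
    # evaluation trial
    eval_locations: tuple = ("ADE", "MIN", "SOS", "WOH", "BOE", "HAD")
    stress_locations: tuple = ("BOE", "HAD")
    eval_years: tuple = (2019,)
    eval_blocks: int = 2
    var_eval_location: float = 4.0
    var_eval_block: float = 1.0
    var_eval_gxe: float = 2.0
    var_eval_residual: float = 5.7
    stress_rho: float = 0.1
    # misc
    seed: int = 1
    n_bootstrap: int = 1000
    run_gxe_diagnostics: bool = True
    select_random: bool = False  # no-selection null: random picks at both stages

    def __post_init__(self) -> None:
        if self.n_c0 > self.n_females:
            raise ValueError("cannot select more C0 females than founders")
        families = self.n_c0
        if self.f2_select_per_family * families > self.f2_total:
            raise ValueError("selected F2 count exceeds the F2 population")
        n_f5 = self.f2_select_per_family * families * self.f5_per_f2
        if self.n_visual > n_f5:
            raise ValueError("visual selection exceeds the F5 population")
        if self.n_c1s > self.n_visual:
            raise ValueError("C1S count exceeds the visually selected set")
        if self.n_testers < 1 or self.n_testers > self.n_males:
            raise ValueError("need between 1 and n_males testers")


@dataclass
class ExperimentReport:
    """All result tables of one simulated cycle."""

    config: ExperimentConfig
    per_plot: pd.DataFrame
    groups: pd.DataFrame  # genotype_id -> group label
    blues_all: pd.Series
    blues_matched: pd.Series
    group_means: pd.DataFrame
    contrasts: pd.DataFrame
    heterosis: pd.DataFrame
    response: dict
    realized_ability: dict
    gxe: dict
    stage_log: list[str] = field(default_factory=list)
    predicted_gca: dict[str, float] = field(default_factory=dict)
    observed_hybrid_means: dict[str, pd.Series] = field(default_factory=dict)


def _meiose_many(
    hap: np.ndarray, geno: GenotypeMatrix, rng: np.random.Generator
) -> np.ndarray:
    return np.stack(
        [
            popgen.meiosis(hap, geno.chrom, geno.pos_cm, rng),
            popgen.meiosis(hap, geno.chrom, geno.pos_cm, rng),
        ]
    )


def run_rrgs_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run one full RRGS cycle; every stage seeded from ``config.seed``."""
    cfg = config
    root = np.random.default_rng(cfg.seed)
    rngs = {
        k: np.random.default_rng(s)
        for k, s in zip(
            ["founders", "arch", "train", "f2", "ssd", "visual", "eval", "boot"],
            root.integers(0, 2**31 - 1, size=8),
        )
    }
    log: list[str] = []

    # --- founders and architecture ---------------------------------------
    females = popgen.make_founders(
        cfg.n_females, cfg.n_markers, cfg.n_chromosomes, cfg.chrom_length_cm,
        cfg.maf_low, cfg.maf_high, seed=rngs["founders"], prefix="F",
    )
    males = popgen.make_founders(
        cfg.n_males, cfg.n_markers, cfg.n_chromosomes, cfg.chrom_length_cm,
        cfg.maf_low, cfg.maf_high, seed=rngs["founders"], prefix="T",
    )
    arch = popgen.make_architecture(
        cfg.n_markers, cfg.n_qtl, cfg.var_additive, cfg.dominance_ratio,
        cfg.intercept, seed=rngs["arch"],
    )
    log.append(f"founders: {cfg.n_females} females x {cfg.n_males} males, "
               f"{cfg.n_markers} markers")

    # --- training population and model fit --------------------------------
    pairs = [(f, m) for f in females.individual_ids for m in males.individual_ids]
    n_keep = int(round(cfg.factorial_fraction * len(pairs)))
    keep_idx = rngs["train"].choice(len(pairs), size=n_keep, replace=False)
    train_pairs = [pairs[i] for i in sorted(keep_idx)]

    fdos = {i: females.row(i) for i in females.individual_ids}
    mdos = {i: males.row(i) for i in males.individual_ids}
    za_rows, zd_rows, gvals = [], [], []
    from .prediction import candidate_design_rows

    for f, m in train_pairs:
        za, zd = candidate_design_rows(fdos[f], mdos[m])
        za_rows.append(za)
        zd_rows.append(zd)
        gvals.append(arch.intercept + za @ arch.additive + zd @ arch.dominance)
    # parent lines are part of the training set (self rows: zero dominance)
    for dos in list(fdos.values()) + list(mdos.values()):
        za_rows.append(dos - 1.0)
        zd_rows.append(np.zeros_like(dos))
        gvals.append(popgen.genetic_value(dos, arch))
    ZA, ZD = np.vstack(za_rows), np.vstack(zd_rows)
    g_train = np.asarray(gvals)
    env_noise_sd = np.sqrt(
        (cfg.var_train_gxe + cfg.var_train_residual) / cfg.n_training_envs
    )
    y_train = g_train + rngs["train"].normal(scale=env_noise_sd, size=len(g_train))
    model = fit_rrblup_ad(y_train, ZA, ZD, varcomp=cfg.rrblup_varcomp)
    log.append(f"training: {len(train_pairs)} hybrids + "
               f"{cfg.n_females + cfg.n_males} lines")

    tester_ids = males.individual_ids[: cfg.n_testers]
    tester_dosage = np.stack([mdos[t] for t in tester_ids])
    all_male_dosage = males.dosage

    def gca_pred(dosages: np.ndarray) -> np.ndarray:
        p = expected_hybrid_matrix(
            dosages, all_male_dosage, model.intercept,
            model.additive_effects, model.dominance_effects,
        )
        return p.mean(axis=1) - p.mean()

    def gca_true(dosages: np.ndarray) -> np.ndarray:
        p = expected_hybrid_matrix(
            dosages, all_male_dosage, arch.intercept, arch.additive, arch.dominance
        )
        return p.mean(axis=1) - p.mean()

    # --- C0 selection and round robin -------------------------------------
    pred_f = gca_pred(females.dosage)
    order = np.argsort(-pred_f)
    c0_ids = [females.individual_ids[i] for i in order[: cfg.n_c0]]
    plan = popgen.round_robin(c0_ids)
    log.append(f"C0: selected {cfg.n_c0} females, round robin of {len(plan)} crosses")

    # --- F2 families and first genomic selection ---------------------------
    base = cfg.f2_total // len(plan)
    sizes = np.full(len(plan), base)
    sizes[: cfg.f2_total - base * len(plan)] += 1
    f2_haps, f2_ids, f2_family = [], [], []
    for fam, ((f, m), size) in enumerate(zip(plan.crosses, sizes)):
        f1 = popgen.cross_haplotypes(fdos[f], fdos[m])
        for k in range(size):
            f2_haps.append(_meiose_many(f1, females, rngs["f2"]))
            f2_ids.append(f"F2_{fam:02d}_{k:03d}")
            f2_family.append(fam)
    f2_dosage = np.stack([h.sum(axis=0) for h in f2_haps])
    f2_family = np.asarray(f2_family)
    pred_f2 = gca_pred(f2_dosage)
    true_f2 = gca_true(f2_dosage)
    acc_f2 = float(np.corrcoef(pred_f2, true_f2)[0, 1])
    score_f2 = rngs["f2"].normal(size=len(pred_f2)) if cfg.select_random else pred_f2
    sel_idx, rand_idx = [], []
    for fam in range(len(plan)):
        members = np.flatnonzero(f2_family == fam)
        top = members[np.argsort(-score_f2[members])][: cfg.f2_select_per_family]
        sel_idx.extend(top)
        rand_idx.extend(
            rngs["f2"].choice(members, size=cfg.f2_select_per_family, replace=False)
        )
    log.append(f"F2: {cfg.f2_total} plants, accuracy {acc_f2:.2f}, "
               f"selected {len(sel_idx)} + {len(rand_idx)} random")

    # --- SSD to F5 and second selection ------------------------------------
    def advance(indices: list[int], tag: str) -> tuple[np.ndarray, list[str], np.ndarray]:
        haps, ids, parent = [], [], []
        for i in indices:
            for k in range(cfg.f5_per_f2):
                h = popgen.self_ssd(
                    f2_haps[i], females.chrom, females.pos_cm,
                    cfg.ssd_generations, rngs["ssd"],
                )
                haps.append(h)
                ids.append(f"{tag}_{f2_ids[i]}_{k:02d}")
                parent.append(i)
        return np.stack([h.sum(axis=0) for h in haps]), ids, np.asarray(parent)

    f5s_dosage, f5s_ids, _ = advance(sel_idx, "S")
    f5r_dosage_full, f5r_ids_full, _ = advance(rand_idx, "R")

    # visual preselection on an auxiliary trait weakly correlated with yield
    g_f5s = popgen.genetic_value(f5s_dosage, arch)
    zg = (g_f5s - g_f5s.mean()) / (g_f5s.std() or 1.0)
    aux = (cfg.visual_aux_correlation * zg
           + np.sqrt(1 - cfg.visual_aux_correlation**2)
           * rngs["visual"].normal(size=len(zg)))
    visual = np.argsort(-aux)[: cfg.n_visual]
    pred_f5 = gca_pred(f5s_dosage[visual])
    true_f5 = gca_true(f5s_dosage[visual])
    acc_f5 = float(np.corrcoef(pred_f5, true_f5)[0, 1])
    score_f5 = (
        rngs["visual"].normal(size=len(pred_f5)) if cfg.select_random else pred_f5
    )
    c1s_local = visual[np.argsort(-score_f5)[: cfg.n_c1s]]
    c1s_ids = [f5s_ids[i] for i in c1s_local]
    c1s_dosage = f5s_dosage[c1s_local]

    r_pick = rngs["visual"].choice(len(f5r_ids_full), size=cfg.n_c1r, replace=False)
    c1r_ids = [f5r_ids_full[i] for i in r_pick]
    c1r_dosage = f5r_dosage_full[r_pick]
    pred_c1r = gca_pred(c1r_dosage)
    log.append(f"F5: visual {cfg.n_visual} of {len(f5s_ids)}, accuracy {acc_f5:.2f}, "
               f"C1S {cfg.n_c1s}, C1R {cfg.n_c1r}")

    # --- evaluation entries -------------------------------------------------
    check_pool = [i for i in females.individual_ids if i not in c0_ids]
    check_ids = list(rngs["eval"].choice(check_pool, size=cfg.n_checks, replace=False))

    entries = []  # (genotype_id, role, group, female, male, gvalue)

    def add_line(gid: str, dosage: np.ndarray, group: str, role: str = "line"):
        entries.append(
            (gid, role, group, None, None, popgen.genetic_value(dosage, arch))
        )

    for gid in c0_ids:
        add_line(gid, fdos[gid], "C0F")
    for gid, dos in zip(c1s_ids, c1s_dosage):
        add_line(gid, dos, "S")
    for gid, dos in zip(c1r_ids, c1r_dosage):
        add_line(gid, dos, "R")
    for gid in tester_ids:
        add_line(gid, mdos[gid], "tester")
    for gid in check_ids:
        add_line(gid, fdos[gid], "check", role="check")

    def add_hybrids(female_ids, female_dosage, group):
        vals = expected_hybrid_matrix(
            female_dosage, tester_dosage, arch.intercept, arch.additive, arch.dominance
        )
        for i, f in enumerate(female_ids):
            for j, t in enumerate(tester_ids):
                entries.append(
                    (f"H_{f}_x_{t}", "hybrid", group, f, t, vals[i, j])
                )

    c0_dosage = np.stack([fdos[i] for i in c0_ids])
    add_hybrids(c0_ids, c0_dosage, "C0H")
    add_hybrids(c1s_ids, c1s_dosage, "C1S")
    add_hybrids(c1r_ids, c1r_dosage, "C1R")

    frame = pd.DataFrame(
        entries,
        columns=["genotype_id", "role", "group", "female_parent", "male_parent", "gvalue"],
    )
    design = TrialDesign(
        locations=list(cfg.eval_locations),
        years=list(cfg.eval_years),
        n_blocks=cfg.eval_blocks,
        var_location=cfg.var_eval_location,
        var_block=cfg.var_eval_block,
        var_gxe=cfg.var_eval_gxe,
        var_residual=cfg.var_eval_residual,
        stress_locations=list(cfg.stress_locations),
        stress_rho=cfg.stress_rho,
    )
    per_plot = popgen.simulate_phenotypes(
        frame[["genotype_id", "role", "female_parent", "male_parent", "gvalue"]],
        design,
        seed=rngs["eval"],
    )
    groups = frame[["genotype_id", "group"]].drop_duplicates()
    per_plot = per_plot.merge(groups, on="genotype_id", how="left")
    log.append(f"evaluation: {len(frame)} entries x {len(design.environments)} "
               f"environments x {cfg.eval_blocks} blocks")

    # --- BLUEs, contrasts, heterosis ---------------------------------------
    matched = per_plot[~per_plot["location"].isin(cfg.stress_locations)]
    blues_all, fit_all = pheno.compute_blues(per_plot)
    blues_matched, _ = pheno.compute_blues(matched)
    gmap = dict(zip(groups["genotype_id"], groups["group"]))

    def summarize(blues: pd.Series) -> pd.DataFrame:
        df = blues.rename("blue").to_frame()
        df["group"] = [gmap[g] for g in df.index]
        return df.groupby("group")["blue"].agg(["mean", "std", "count"])

    group_means = pd.concat(
        {"all_envs": summarize(blues_all), "matched_envs": summarize(blues_matched)},
        names=["environments", "group"],
    ).reset_index()

    pairs_to_test = [("C1S", "C1R"), ("C1S", "C0H"), ("C1R", "C0H"), ("S", "C0F")]
    contrasts = pd.concat(
        [
            group_contrasts(blues, gmap, pairs_to_test,
                            n_bootstrap=cfg.n_bootstrap, seed=rngs["boot"]).assign(
                environments=tag)
            for tag, blues in (("all_envs", blues_all), ("matched_envs", blues_matched))
        ],
        ignore_index=True,
    )

    het_rows = []
    for tag, blues in (("all_envs", blues_all), ("matched_envs", blues_matched)):
        for _, row in frame[frame["role"] == "hybrid"].iterrows():
            try:
                h = pheno.heterosis(
                    blues[row["genotype_id"]],
                    blues[row["female_parent"]],
                    blues[row["male_parent"]],
                    hybrid_id=row["genotype_id"],
                )
            except KeyError:
                continue
            het_rows.append(
                {"environments": tag, "hybrid": h.hybrid_id, "group": row["group"],
                 "mph": h.mph, "bph": h.bph}
            )
    heterosis = pd.DataFrame(het_rows)

    # --- response to selection ---------------------------------------------
    sigma_f2 = float(np.std(true_f2, ddof=1))
    within = [np.std(true_f2[f2_family == fam], ddof=1) for fam in range(len(plan))]
    sigma_step1 = float(np.sqrt(np.mean(np.square(within))))
    sigma_step2 = float(np.std(true_f5, ddof=1))
    steps = [
        selection.SelectionStep(
            N=len(sel_idx), G=cfg.f2_total, h=max(min(acc_f2, 1.0), 0.0),
            sigma_a=sigma_step1),
        selection.SelectionStep(
            N=cfg.n_c1s, G=cfg.n_visual, h=max(min(acc_f5, 1.0), 0.0),
            sigma_a=sigma_step2),
    ]
    r_exp = selection.expected_response(steps)

    def hybrid_group_mean(blues: pd.Series, group: str) -> float:
        ids = [g for g, gr in gmap.items() if gr == group and g in blues.index]
        return float(blues[ids].mean())

    response = {
        "R_exp": r_exp.total_expected,
        "R_exp_steps": r_exp.step_responses,
        "intensities": r_exp.intensities,
        "accuracy_f2": acc_f2,
        "accuracy_f5": acc_f5,
        "sigma_gca_f2_within": sigma_step1,
        "sigma_gca_f2_total": sigma_f2,
        "sigma_gca_f56": sigma_step2,
        "R_obs_all_envs": selection.observed_response(
            hybrid_group_mean(blues_all, "C1S"), hybrid_group_mean(blues_all, "C0H")),
        "R_obs_matched_envs": selection.observed_response(
            hybrid_group_mean(blues_matched, "C1S"),
            hybrid_group_mean(blues_matched, "C0H")),
    }

    # --- realized prediction ability ---------------------------------------
    predicted_gca = dict(zip(c1r_ids, map(float, pred_c1r)))
    observed_means = {}
    for tag, blues in (("all_envs", blues_all), ("matched_envs", blues_matched)):
        hyb = frame[(frame["role"] == "hybrid") & (frame["group"] == "C1R")]
        means = {
            f: blues[grp["genotype_id"]].mean()
            for f, grp in hyb.groupby("female_parent")
        }
        observed_means[tag] = pd.Series(means)
    report = ExperimentReport(
        config=cfg,
        per_plot=per_plot,
        groups=groups,
        blues_all=blues_all,
        blues_matched=blues_matched,
        group_means=group_means,
        contrasts=contrasts,
        heterosis=heterosis,
        response=response,
        realized_ability={},
        gxe={},
        stage_log=log,
        predicted_gca=predicted_gca,
        observed_hybrid_means=observed_means,
    )
    report.realized_ability = {
        tag: realized_prediction_ability(report, which=tag)
        for tag in ("all_envs", "matched_envs")
    }

    # --- G x E diagnostics ---------------------------------------------------
    if not cfg.run_gxe_diagnostics:
        report.gxe = {"skipped": True}
        return report
    try:
        vc, vcfit = pheno.fit_variance_components(per_plot)
        effects = gxe_mod.interaction_effects(vcfit)
        dists = gxe_mod.euclidean_distances(effects, axis="columns")
        Z, flat = gxe_mod.complete_linkage(dists, n_clusters=2)
        profiles = popgen.simulate_env_profiles(design, seed=rngs["eval"])
        prof_d = gxe_mod.profile_distances(profiles, on="vci")
        # align profile distances (per location) with interaction distances
        env_locs = [e.rsplit("_", 1)[0] for e in dists.ids]
        order = [prof_d.ids.index(loc) for loc in env_locs]
        prof_aligned = gxe_mod.DistanceMatrix(
            ids=dists.ids, values=prof_d.values[np.ix_(order, order)]
        )
        r, p = gxe_mod.mantel(dists, prof_aligned, n_permutations=999,
                              seed=int(rngs["boot"].integers(2**31 - 1)))
        report.gxe = {
            "variance_components": vc.to_dict(),
            "gca_female_env_distances": dists,
            "clusters": flat,
            "mantel_r": r,
            "mantel_p": p,
        }
    except Exception as err:  # diagnostics failing should not void the cycle
        report.gxe = {"error": f"{type(err).__name__}: {err}"}
        log.append(f"gxe diagnostics failed: {err}")
    return report


def realized_prediction_ability(
    report: ExperimentReport, group: str = "C1R", which: str = "matched_envs"
) -> float:
    """Correlation of predicted GCA and observed mean hybrid performance.

    Computed over the female parents of the control group (predictions were
    stored at selection time; observations are the BLUE means of each
    female's testcross hybrids).
    """
    if group != "C1R":
        raise ValueError("predictions are stored for the random control group only")
    obs = report.observed_hybrid_means[which]
    if len(obs) < 3:
        raise ValueError("group smaller than 3")
    pred = pd.Series(report.predicted_gca).reindex(obs.index)
    return float(np.corrcoef(pred.to_numpy(), obs.to_numpy())[0, 1])


def group_contrasts(
    blues: pd.Series,
    group_of: dict[str, str],
    pairs: list[tuple[str, str]],
    n_bootstrap: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pairwise group mean differences with genotype-level bootstrap.

    For each (A, B) pair the difference of group BLUE means is reported
    with a percentile interval and a two-sided bootstrap p-value obtained
    by resampling genotypes within groups.
    """
    rng = np.random.default_rng(seed)
    values = {g: [] for g in set(group_of.values())}
    for gid, grp in group_of.items():
        if gid in blues.index:
            values[grp].append(blues[gid])
    rows = []
    for a, b in pairs:
        xa = np.asarray(values.get(a, []), dtype=float)
        xb = np.asarray(values.get(b, []), dtype=float)
        if len(xa) == 0 or len(xb) == 0:
            raise ValueError(f"empty group in contrast ({a}, {b})")
        diff = xa.mean() - xb.mean()
        boots = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            boots[i] = (
                rng.choice(xa, size=len(xa)).mean()
                - rng.choice(xb, size=len(xb)).mean()
            )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        p = 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())
        rows.append(
            {"group_a": a, "group_b": b, "difference": diff,
             "ci_low": lo, "ci_high": hi, "p_boot": min(p, 1.0),
             "n_a": len(xa), "n_b": len(xb)}
        )
    return pd.DataFrame(rows)


def scaled_down_config(seed: int = 1, **overrides) -> ExperimentConfig:
    """A small but structurally faithful configuration for fast studies.

    Keeps the two-step selection geometry and the stressed evaluation
    subset while shrinking population sizes and marker counts so a full
    cycle runs in seconds.
    """
    base = dict(
        n_females=36, n_males=6, n_markers=180, n_chromosomes=6,
        chrom_length_cm=120.0, n_qtl=90, factorial_fraction=0.6,
        n_c0=10, f2_total=120, f2_select_per_family=3, f5_per_f2=3,
        n_visual=72, n_c1s=20, n_c1r=12, n_testers=3, n_checks=4,
        rrblup_varcomp=(0.04, 0.015, 1.3),
        n_bootstrap=300, seed=seed,
    )
    base.update(overrides)
    return ExperimentConfig(**base)
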