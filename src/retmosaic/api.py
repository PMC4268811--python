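"""High-level orchestration: cohort tables, per-stage reports, end-to-end runs.

These functions tie the per-module operations into the cohort-level
analyses: per-retina type counts and percentages, join-count tables,
density surfaces, region-enrichment G-tests per (strain, sex), fixed-
effect ANOVA of percentages and totals, and the qPCR index + LMM stage.
The command-line interface and the example scripts are thin wrappers
around them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .group_stats import (
    LmmFit,
    LrtResult,
    fit_random_intercept_lmm,
    lrt,
    marginal_f_test,
    ols_fit,
    simple_regression,
)
from .mosaic_model import (
    RetinalMosaicMap,
    count_types,
    percent_p_oc,
    read_mosaic_map,
    write_mosaic_map,
)
from .qpcr_expression import QpcrDataset, index_table
from .region_analysis import (
    partition,
    region_enrichment,
    region_table,
    repeated_g_test,
)
from .spatial_stats import (
    JoinCountResult,
    hex_adjacency,
    join_count_test,
    kernel_density,
    strip_marks,
)
from .mosaic_model import to_point_pattern


def cohort_counts_table(maps: Sequence[RetinalMosaicMap]) -> pd.DataFrame:
    """Per-retina type counts, total and p+OC percentage for a cohort."""
    rows = []
    for m in maps:
        c = count_types(m)
        rows.append(
            {
                "retina_id": m.metadata.get("retina_id"),
                "species": m.metadata.get("species"),
                "strain": m.metadata.get("strain"),
                "sex": m.metadata.get("sex"),
                "n_p_oc": c.n_p_oc,
                "n_y": c.n_y,
                "n_dra": c.n_dra,
                "n_unknown": c.n_unknown,
                "n_total": c.n_total,
                "pct_p_oc": percent_p_oc(c),
            }
        )
    return pd.DataFrame(rows)


def join_count_table(
    maps: Sequence[RetinalMosaicMap],
    method: str = "both",
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Join-count inference per retina x type pair, as a tidy table."""
    rows = []
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(maps))
    for m, ss in zip(maps, streams):
        graph, marks = strip_marks(hex_adjacency(m), m)
        res = join_count_test(
            graph,
            marks,
            method=method,
            n_perm=n_perm,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        for pair, st in res.pairs.items():
            rows.append(
                {
                    "retina_id": m.metadata.get("retina_id"),
                    "strain": m.metadata.get("strain"),
                    "sex": m.metadata.get("sex"),
                    "pair": pair,
                    "j_obs": st.j_obs,
                    "e_j": st.e_j,
                    "var_j": st.var_j,
                    "z": st.z,
                    "p_analytic": st.p_analytic,
                    "p_perm": st.p_perm,
                }
            )
    return pd.DataFrame(rows)


def region_test_report(
    maps: Sequence[RetinalMosaicMap],
    axis: Literal["dorsoventral", "anteroposterior"],
    williams: bool = False,
) -> pd.DataFrame:
    """Per-(strain, sex) enrichment deviations and repeated G-tests.

    The focal region is dorsal (DV axis) or anterior (AP axis), matching
    the reporting convention in which the opposite half's deviation is
    (approximately) the negative.  Heterogeneity among replicate retinas
    is screened and flagged; the pooled test is reported regardless.
    """
    focal = "dorsal" if axis == "dorsoventral" else "anterior"
    rows = []
    df_meta = pd.DataFrame(
        {
            "strain": [m.metadata.get("strain") for m in maps],
            "sex": [m.metadata.get("sex") for m in maps],
        }
    )
    for (strain, sex), idx in df_meta.groupby(["strain", "sex"]).groups.items():
        group = [maps[i] for i in idx]
        tables, devs, ids = [], [], []
        for m in group:
            part = partition(m, axis)
            tables.append(region_table(m, part))
            devs.append(region_enrichment(m, part, focal))
            ids.append(m.metadata.get("retina_id"))
        row = {
            "strain": strain,
            "sex": sex,
            "axis": axis,
            "n_retinas": len(group),
            "mean_deviation": float(np.mean(devs)),
            "deviations": devs,
            "retina_ids": ids,
        }
        if len(tables) >= 2:
            rep = repeated_g_test(tables, williams=williams, table_ids=ids)
            row.update(
                g_pooled=rep.pooled.g,
                df_pooled=rep.pooled.df,
                p_pooled=rep.pooled.p,
                g_het=rep.heterogeneity.g,
                df_het=rep.heterogeneity.df,
                p_het=rep.heterogeneity.p,
                het_flag=rep.heterogeneity_significant,
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortStatsReport:
    """Fixed-effect model results for one cohort counts table."""

    proportion_anova: pd.DataFrame
    totals_overall_f: float
    totals_overall_p: float
    totals_overall_df: tuple[int, int]
    sex_coefficient_total: float
    sex_coefficient_se: float
    sex_marginal_f: float
    sex_marginal_p: float
    dra_mean: float
    dra_sd: float
    dra_overall_f: float
    dra_overall_p: float
    regression_slope: float
    regression_r2: float
    regression_f: float
    regression_p: float


def cohort_statistics(
    counts: pd.DataFrame, anova_order: Sequence[str] = ("sex", "strain", "sex:strain")
) -> CohortStatsReport:
    """The cohort-level fixed-effect analyses on a per-retina counts table.

    * p+OC percentage ~ sex + strain + sex:strain, sequential ANOVA in
      ``anova_order`` (sex entered first by default);
    * total ommatidia ~ strain + sex (additive): overall regression F,
      and the marginal (drop-one) F and treatment coefficient for sex;
    * DRA count ~ strain + sex: overall F (tests any group structure);
    * simple regression of p+OC percentage on total ommatidia.

    ``counts`` must have columns strain, sex, pct_p_oc, n_total, n_dra.
    """
    _, prop_aov = ols_fit(counts, "pct_p_oc", list(anova_order))

    import statsmodels.formula.api as smf
    from scipy import stats as sps

    additive = smf.ols("n_total ~ strain + sex", data=counts).fit()
    df_model = int(additive.df_model)
    df_resid = int(additive.df_resid)
    f_overall = float(additive.fvalue)
    p_overall = float(additive.f_pvalue)
    sex_terms = [n for n in additive.params.index if n.startswith("sex[")]
    sex_coef = float(additive.params[sex_terms[0]])
    sex_se = float(additive.bse[sex_terms[0]])
    _, f_sex, p_sex, _, _ = marginal_f_test(
        counts, "n_total", ["strain", "sex"], "sex"
    )

    dra_fit = smf.ols("n_dra ~ strain + sex", data=counts).fit()

    slope, r2, f_reg, p_reg = simple_regression(counts["pct_p_oc"], counts["n_total"])

    return CohortStatsReport(
        proportion_anova=prop_aov.to_frame(),
        totals_overall_f=f_overall,
        totals_overall_p=p_overall,
        totals_overall_df=(df_model, df_resid),
        sex_coefficient_total=sex_coef,
        sex_coefficient_se=sex_se,
        sex_marginal_f=float(f_sex),
        sex_marginal_p=float(p_sex),
        dra_mean=float(counts["n_dra"].mean()),
        dra_sd=float(counts["n_dra"].std(ddof=1)),
        dra_overall_f=float(dra_fit.fvalue),
        dra_overall_p=float(dra_fit.f_pvalue),
        regression_slope=slope,
        regression_r2=r2,
        regression_f=f_reg,
        regression_p=p_reg,
    )


@dataclass
class QpcrReport:
    """Indexes plus LMM/LRT results for one qPCR dataset."""

    indexes: pd.DataFrame
    lmm_fits: dict[str, LmmFit]
    sex_lrt: dict[str, LrtResult]
    species_lrt: dict[str, LrtResult]


def qpcr_analysis(dataset: QpcrDataset) -> QpcrReport:
    """rh3/rh5 indexes and the mixed-model comparisons of sex and species.

    For each index, a Gaussian LMM with species and sex fixed (no
    interaction) and random intercepts for strain and biological
    replicate is fitted by ML; sex and species are each tested by a
    likelihood-ratio chi-square against the model without that term.
    Biological replicates are nested within strains (replicate "a" of
    one strain is a different fly collection from replicate "a" of
    another), so the replicate grouping column is strain:bio_rep.
    """
    idx = index_table(dataset)
    fits: dict[str, LmmFit] = {}
    sex_tests: dict[str, LrtResult] = {}
    species_tests: dict[str, LrtResult] = {}
    for index_id, sub in idx.groupby("index_id"):
        sub = sub.reset_index(drop=True)
        sub = sub.assign(rep_in_strain=sub["strain"] + ":" + sub["bio_rep"])
        groups = ["strain", "rep_in_strain"]
        full = fit_random_intercept_lmm(sub, "value", ["species", "sex"], groups)
        no_sex = fit_random_intercept_lmm(sub, "value", ["species"], groups)
        no_species = fit_random_intercept_lmm(sub, "value", ["sex"], groups)
        fits[index_id] = full
        sex_tests[index_id] = lrt(full, no_sex)
        species_tests[index_id] = lrt(full, no_species)
    return QpcrReport(
        indexes=idx, lmm_fits=fits, sex_lrt=sex_tests, species_lrt=species_tests
    )


def write_density_grids(
    maps: Sequence[RetinalMosaicMap],
    out_dir: str | Path,
    sigma: float = 70.0,
    cell: float = 10.0,
    render_png: bool = False,
) -> list[Path]:
    """p+OC kernel density surface per retina as matrix TSV + JSON header."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for m in maps:
        rid = m.metadata.get("retina_id", "x")
        pattern = to_point_pattern(m)
        grid = kernel_density(
            pattern, type_filter="P_OC", sigma=sigma, cell=cell, canvas=m.canvas
        )
        base = out_dir / f"density_retina_{rid}"
        grid.to_tsv(base.with_suffix(".tsv"))
        header = {
            "retina_id": rid,
            "sigma_px": sigma,
            "cell_px": cell,
            "edge_correction": grid.edge_correction,
            "display_range": list(grid.display_range),
            "integral": grid.integral(),
            "module_version": __version__,
        }
        base.with_suffix(".json").write_text(json.dumps(header, indent=1))
        if render_png:
            grid.render(base.with_suffix(".png"))
        written.append(base.with_suffix(".tsv"))
    return written
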