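"""Primer efficiencies, efficiency-corrected quantities and rhodopsin indexes.

Relative rhodopsin transcript abundance is summarised without a
housekeeping gene by pairing the two genes that distinguish the R7 / R8
cells of the two stochastic ommatidium types:

* rh3 index = 100 * rh3 / (rh3 + rh4)   (R7: pale vs yellow),
* rh5 index = 100 * rh5 / (rh5 + rh6)   (R8: pale vs yellow),

where each gene's quantity is the efficiency-corrected transform of its
quantification cycle, Q = E ** (-Cq), with E the per-cycle amplification
factor of that primer pair estimated from a dilution series.  Because
the indexes are ratios of quantities measured in the same cDNA pool,
any global scaling (template amount, C0 offset) cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mosaic_model import UndefinedValueError

QPCR_COLUMNS = ("species", "strain", "sex", "bio_rep", "gene", "tech_rep", "cq")
#: Genes excluded from quantification when present (negative controls).
CONTROL_GENES = ("no_rt", "water", "ntc")

INDEX_PAIRS = {"rh3_index": ("rh3", "rh4"), "rh5_index": ("rh5", "rh6")}
THREE_GENE_SET = ("rh3", "rh4", "rh6")


class QpcrFormatError(ValueError):
    """A qPCR table does not conform to the long format."""


class EfficiencyError(ValueError):
    """A dilution series yields no usable primer efficiency."""


@dataclass
class QpcrDataset:
    """Long-format Cq table plus per-gene primer efficiencies.

    ``data`` columns: species, strain, sex, bio_rep, gene, tech_rep, cq.
    Control rows (gene in :data:`CONTROL_GENES`) are retained in ``data``
    but excluded from all quantification.
    """

    data: pd.DataFrame
    efficiencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in QPCR_COLUMNS if c not in self.data.columns]
        if missing:
            raise QpcrFormatError(f"qPCR table missing column(s) {missing}")
        quant = self.quantified()
        if len(quant) and not np.isfinite(quant["cq"]).all():
            raise QpcrFormatError("non-finite Cq value in quantified rows")
        if len(quant) and (quant["cq"] <= 0).any():
            raise QpcrFormatError("Cq values must be positive")
        for g, e in self.efficiencies.items():
            if not (1.0 < e <= 2.2):
                raise QpcrFormatError(f"primer efficiency {g}={e} outside (1, 2.2]")

    def quantified(self) -> pd.DataFrame:
        """Rows entering quantification (negative controls excluded)."""
        return self.data[~self.data["gene"].isin(CONTROL_GENES)]

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(
        cls, path: str | Path, efficiencies: Mapping[str, float] | None = None
    ) -> "QpcrDataset":
        df = pd.read_csv(path, sep="\t")
        return cls(data=df, efficiencies=dict(efficiencies or {}))


def primer_efficiency(dilutions: Sequence[tuple[float, float]]) -> float:
    """Per-cycle amplification factor from a cDNA dilution series.

    ``dilutions`` holds (dilution_factor, Cq) points, e.g. (4, Cq) for a
    1:4 dilution; relative concentration is 1/dilution_factor.  The
    efficiency is E = 10 ** (-1/m) with m the least-squares slope of Cq
    on log10(relative concentration); perfect doubling gives a slope of
    -1/log10(2) ~ -3.32 and E = 2.

    Raises :class:`EfficiencyError` for <3 points, non-distinct
    dilutions, or |slope| < 1e-6 (Cq independent of dilution).  An
    estimate outside (1, 2.2] is returned but flagged with a warning.
    """
    if len(dilutions) < 3:
        raise EfficiencyError("need at least 3 dilution points")
    fac = np.array([d for d, _ in dilutions], dtype=float)
    cq = np.array([c for _, c in dilutions], dtype=float)
    if len(np.unique(fac)) < len(fac):
        raise EfficiencyError("dilution factors must be distinct")
    logc = np.log10(1.0 / fac)
    slope, _, _, _, _ = stats.linregress(logc, cq)
    if abs(slope) < 1e-6:
        raise EfficiencyError("Cq does not depend on dilution; no efficiency")
    eff = 10.0 ** (-1.0 / slope)
    if not (1.0 < eff <= 2.2):
        import warnings

        warnings.warn(
            f"estimated efficiency {eff:.4f} outside the plausible (1, 2.2] range",
            stacklevel=2,
        )
    return float(eff)


def relative_quantity(cq: float | np.ndarray, efficiency: float) -> float | np.ndarray:
    """Efficiency-corrected relative template quantity, Q = E ** (-Cq)."""
    if not (1.0 < efficiency <= 2.2):
        raise ValueError(f"efficiency {efficiency} outside (1, 2.2]")
    return efficiency ** (-np.asarray(cq, dtype=float))


def expression_index(q_num: float, q_partner: float) -> float:
    """Percentage of one quantity relative to itself plus its partner."""
    total = q_num + q_partner
    if total <= 0:
        raise UndefinedValueError("zero total quantity: index undefined")
    return 100.0 * q_num / total


def _efficiency(efficiencies: Mapping[str, float], gene: str) -> float:
    e = efficiencies.get(gene)
    if e is None:
        raise QpcrFormatError(f"no primer efficiency for gene {gene!r}")
    return e


def index_table(
    dataset: QpcrDataset,
    average_cq_first: bool = True,
) -> pd.DataFrame:
    """Per-bio-replicate rh3 and rh5 indexes, with technical-replicate spread.

    For each (species, strain, sex, bio_rep) group and each index pair,
    technical replicates are paired by replicate number to give four
    per-tech-rep indexes (the within-replicate spread); the headline
    per-bio-rep value averages Cq across technical replicates before the
    quantity transform (``average_cq_first=True``, the default) or
    averages the per-tech-rep indexes (``False``).

    Groups missing one partner gene are skipped (recorded in the
    DataFrame ``attrs['skipped']``).  The three-gene shares
    rh3/rh4/rh6 : (rh3+rh4+rh6) are included as extra columns where all
    three genes are present.

    Returns a tidy DataFrame with one row per (group, bio_rep, index_id):
    columns species, strain, sex, bio_rep, index_id, value,
    tech_values (list), tech_sd.
    """
    df = dataset.quantified()
    rows = []
    skipped = []
    group_cols = ["species", "strain", "sex", "bio_rep"]
    for keys, grp in df.groupby(group_cols, sort=True):
        genes = {
            g: sub.set_index("tech_rep")["cq"]
            for g, sub in grp.groupby("gene")
        }
        for index_id, (g_num, g_den) in INDEX_PAIRS.items():
            if g_num not in genes or g_den not in genes:
                skipped.append((keys, index_id, "missing partner gene"))
                continue
            e_num = _efficiency(dataset.efficiencies, g_num)
            e_den = _efficiency(dataset.efficiencies, g_den)
            common = genes[g_num].index.intersection(genes[g_den].index)
            tech_vals = [
                expression_index(
                    relative_quantity(genes[g_num][t], e_num),
                    relative_quantity(genes[g_den][t], e_den),
                )
                for t in sorted(common)
            ]
            if average_cq_first:
                value = expression_index(
                    relative_quantity(genes[g_num].mean(), e_num),
                    relative_quantity(genes[g_den].mean(), e_den),
                )
            else:
                value = float(np.mean(tech_vals))
            row = dict(zip(group_cols, keys))
            row.update(
                index_id=index_id,
                value=value,
                tech_values=tech_vals,
                tech_sd=float(np.std(tech_vals, ddof=1)) if len(tech_vals) > 1 else 0.0,
            )
            # three-gene representation alongside the rh3 index row
            if index_id == "rh3_index" and all(g in genes for g in THREE_GENE_SET):
                qs = {
                    g: relative_quantity(
                        genes[g].mean(), _efficiency(dataset.efficiencies, g)
                    )
                    for g in THREE_GENE_SET
                }
                total = sum(qs.values())
                for g in THREE_GENE_SET:
                    row[f"share_{g}_of_346"] = 100.0 * qs[g] / total
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


def efficiency_report(
    series: Mapping[str, Sequence[tuple[float, float]]]
) -> pd.DataFrame:
    """Primer efficiencies for several genes' dilution series as a table."""
    rows = []
    for gene, dil in series.items():
        rows.append({"gene": gene, "efficiency": primer_efficiency(dil), "n_points": len(dil)})
    return pd.DataFrame(rows)
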