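"""Cross-classification statistics: Fisher exact enrichment, the length-restricted
age comparison, and the logistic gene-youth regression.

All enrichment tests are computed over genes with significant expression
(low-expression-filtered and unexpressed genes are excluded).  P-values are
reported raw, without correction across the battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .de import STATUS_UP
from .families import ParalogFamily, multi_copy_flags
from .io_tables import ProteinRecord, Stratum, gene_lengths
from .strata import StratumAssignment, expression_class, stratum_table

__all__ = [
    "ContingencyTable2x2",
    "LogisticFit",
    "fisher_exact_2x2",
    "class_enrichment",
    "iqr_restricted_comparison",
    "logistic_youth_model",
]

IQR_LOW_DEFAULT = 134  # induced-class protein-length interquartile range, inclusive
IQR_HIGH_DEFAULT = 456


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = class membership (in/out), columns = property (yes/no)."""

    a: int  # in class, property yes
    b: int  # in class, property no
    c: int  # out of class, property yes
    d: int  # out of class, property no

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def has_zero_margin(self) -> bool:
        m = self.as_array()
        return bool((m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any())


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test by the minimum-likelihood rule.

    Returns the sample odds ratio (a*d)/(b*c) — infinity when b*c = 0 and
    a*d > 0, nan for the doubly degenerate table — and the two-sided p-value.
    A zero margin yields p = 1 by convention.
    """
    if table.has_zero_margin:
        warnings.warn("Fisher test on a table with a zero margin; p = 1 by convention")
        p = 1.0
    else:
        _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        odds = float("nan") if ad == 0 else float("inf")
    else:
        odds = ad / bc
    return odds, float(p)


def _induction_test(
    name: str,
    in_class: pd.Series,
    induced: pd.Series,
) -> dict | None:
    """One battery row: is induction enriched in `in_class` vs the rest?"""
    n_class = int(in_class.sum())
    n_rest = int((~in_class).sum())
    if n_class == 0 or n_rest == 0:
        warnings.warn(f"enrichment comparison {name!r} skipped: empty class")
        return None
    a = int((in_class & induced).sum())
    b = n_class - a
    c = int((~in_class & induced).sum())
    d = n_rest - c
    table = ContingencyTable2x2(a, b, c, d)
    odds, p = fisher_exact_2x2(table)
    return {
        "comparison": name,
        "a": a,
        "b": b,
        "c": c,
        "d": d,
        "prop_class": a / n_class,
        "prop_rest": c / n_rest,
        "odds_ratio": odds,
        "pvalue": p,
    }


def class_enrichment(
    de_results: pd.DataFrame,
    immune_annotations: Mapping[str, object],
    assignments: Mapping[str, StratumAssignment],
    families: Sequence[ParalogFamily],
    proteins: Sequence[ProteinRecord],
    signal_flags: Mapping[str, bool],
    max_len: int = 300,
) -> pd.DataFrame:
    """The full Fisher battery of induction-enrichment comparisons.

    For each gene property (immune membership, each immune class, signal
    peptide, short protein, multi-copy family, Metazoan vs younger, Wasp vs
    non-Wasp) a 2×2 table of property × induced is built over expressed genes
    and tested.  Returns one row per comparison.
    """
    expressed = de_results[
        de_results["status"].map(lambda s: expression_class(s) is not None)
    ]
    genes = expressed.index
    induced = pd.Series(
        [expressed.loc[g, "status"] == STATUS_UP for g in genes], index=genes
    )
    lengths = gene_lengths(proteins)
    multi = multi_copy_flags(families)

    immune = pd.Series([g in immune_annotations for g in genes], index=genes)
    comparisons: list[tuple[str, pd.Series]] = [("immune_vs_nonimmune", immune)]
    classes = {}
    for g in genes:
        ann = immune_annotations.get(g)
        classes[g] = getattr(ann, "immune_class", None)
    for cls in sorted({c for c in classes.values() if c is not None}):
        comparisons.append(
            (f"class_{cls}", pd.Series([classes[g] == cls for g in genes], index=genes))
        )
    comparisons += [
        (
            "signal_peptide",
            pd.Series([bool(signal_flags.get(g, False)) for g in genes], index=genes),
        ),
        (
            f"length_lt_{max_len}",
            pd.Series([lengths.get(g, max_len) < max_len for g in genes], index=genes),
        ),
        (
            "multi_copy_family",
            pd.Series([multi.get(g, False) for g in genes], index=genes),
        ),
    ]
    if assignments:
        strata = {g: assignments[g].stratum for g in genes if g in assignments}
        covered = pd.Series([g in strata for g in genes], index=genes)
        metazoan = pd.Series(
            [strata.get(g) == Stratum.METAZOAN for g in genes], index=genes
        )[covered]
        wasp = pd.Series([strata.get(g) == Stratum.WASP for g in genes], index=genes)[
            covered
        ]
        rows = []
        for name, flag in comparisons:
            row = _induction_test(name, flag, induced)
            if row:
                rows.append(row)
        for name, flag in [("stratum_metazoan", metazoan), ("stratum_wasp", wasp)]:
            row = _induction_test(name, flag, induced[covered])
            if row:
                rows.append(row)
    else:
        rows = [r for name, flag in comparisons if (r := _induction_test(name, flag, induced))]
    return pd.DataFrame(rows).set_index("comparison")


def iqr_restricted_comparison(
    assignments: Mapping[str, StratumAssignment],
    de_results: pd.DataFrame,
    proteins: Sequence[ProteinRecord],
    low: int = IQR_LOW_DEFAULT,
    high: int = IQR_HIGH_DEFAULT,
) -> dict:
    """Stratum × expression-class table restricted to mid-length proteins.

    Controls the age–length confound by keeping only genes whose protein
    length lies in [low, high] (inclusive), by default the interquartile range
    of the induced class.  Also reports the IQR computed from the data at hand
    next to the configured bounds.
    """
    lengths = gene_lengths(proteins)
    keep = [
        g
        for g in de_results.index
        if g in lengths and low <= lengths[g] <= high
    ]
    if not keep:
        raise ValueError(f"no genes with protein length in [{low}, {high}]")
    restricted = de_results.loc[keep]
    counts, props = stratum_table(assignments, restricted)

    induced_lengths = [
        lengths[g]
        for g in de_results.index
        if de_results.loc[g, "status"] == STATUS_UP and g in lengths
    ]
    if induced_lengths:
        q1, q3 = np.percentile(induced_lengths, [25, 75])
        computed = (float(q1), float(q3))
    else:
        computed = (float("nan"), float("nan"))
    return {
        "counts": counts,
        "proportions": props,
        "configured_bounds": (low, high),
        "computed_induced_iqr": computed,
        "n_genes": len(keep),
    }


@dataclass(frozen=True)
class LogisticFit:
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    pvalues: dict[str, float]
    converged: bool
    n_obs: int
    youth_definition: str


def logistic_youth_model(
    assignments: Mapping[str, StratumAssignment],
    de_results: pd.DataFrame,
    proteins: Sequence[ProteinRecord],
    youth_definition: str = "not_metazoan",
) -> LogisticFit:
    """Logistic regression of gene youth on induction and protein size.

    The response is 1 for a "young" gene — not reaching the Metazoan stratum
    (default) or Wasp-restricted (``youth_definition="wasp_specific"``) — and
    0 otherwise; predictors are an induced indicator and raw protein length in
    amino acids.  A positive induced coefficient therefore means induced genes
    are younger.  Fitted by Newton/IRLS maximum likelihood with Wald p-values.
    """
    if youth_definition not in ("not_metazoan", "wasp_specific"):
        raise ValueError(f"unknown youth definition {youth_definition!r}")
    lengths = gene_lengths(proteins)
    rows = []
    for g in de_results.index:
        cls = expression_class(de_results.loc[g, "status"])
        if cls is None or g not in assignments or g not in lengths:
            continue
        stratum = assignments[g].stratum
        young = (
            stratum != Stratum.METAZOAN
            if youth_definition == "not_metazoan"
            else stratum == Stratum.WASP
        )
        rows.append((int(young), int(cls == "induced"), lengths[g]))
    data = pd.DataFrame(rows, columns=["young", "induced", "size_aa"])
    n_young = int(data["young"].sum())
    if min(n_young, len(data) - n_young) < 50:
        raise ValueError(
            f"too few genes per response level ({n_young} young / "
            f"{len(data) - n_young} old; need >= 50 each)"
        )
    X = sm.add_constant(data[["induced", "size_aa"]].astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.Logit(data["young"].astype(float), X).fit(disp=False, maxiter=200)
        except Exception as exc:  # separation or non-convergence
            raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 1e3:
        raise ValueError("logistic fit did not converge; a coefficient may be diverging")
    names = {"const": "intercept", "induced": "induced", "size_aa": "size_aa"}
    return LogisticFit(
        coefficients={names[k]: float(v) for k, v in fit.params.items()},
        std_errors={names[k]: float(v) for k, v in fit.bse.items()},
        pvalues={names[k]: float(v) for k, v in fit.pvalues.items()},
        converged=True,
        n_obs=len(data),
        youth_definition=youth_definition,
    )
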