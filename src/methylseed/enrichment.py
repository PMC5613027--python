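"""GO term over/under-representation by the hypergeometric test.

For a selection of n genes from a background of N, a term annotating K
background genes and observed on k selected genes has expected count
K*n/N.  Over-representation uses the upper hypergeometric tail
P(X >= k), under-representation the lower tail P(X <= k); the direction is
chosen by comparing k with its expectation.  P-values are corrected across
all tested terms (Benjamini-Hochberg by default, Bonferroni selectable) and
flagged significant below a corrected-probability cut of 0.01.

The annotation map is taken as given: no GO-graph ancestor propagation.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["go_enrichment"]

ENRICHMENT_COLUMNS = [
    "go_id",
    "genome_count",
    "observed",
    "expected",
    "representation",
    "raw_p",
    "corrected_p",
    "significant",
    "go_description",
]


def go_enrichment(
    selected: set[str],
    background: set[str],
    annotation: pd.DataFrame,
    method: str = "fdr_bh",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-term enrichment table for a gene selection against a background.

    ``annotation`` has columns gene_id, go_id, go_description; annotations
    of genes outside the background are ignored.  Rows are sorted by
    corrected then raw p-value.
    """
    if not selected or not background:
        raise ValueError("selection and background must be non-empty")
    if not selected <= background:
        raise ValueError("selection must be a subset of the background")
    ann = annotation[annotation["gene_id"].isin(background)]
    if len(ann) == 0:
        raise ValueError("annotation covers no background gene")
    n_bg = len(background)
    n_sel = len(selected)
    desc = (
        ann.drop_duplicates("go_id").set_index("go_id")["go_description"].to_dict()
    )
    rows = []
    for go_id, grp in ann.groupby("go_id", sort=True):
        term_genes = set(grp["gene_id"])
        big_k = len(term_genes)
        k = len(term_genes & selected)
        expected = big_k * n_sel / n_bg
        if k > expected:
            representation = "Overrepresented"
            raw_p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_sel))
        else:
            representation = "Underrepresented"
            raw_p = float(stats.hypergeom.cdf(k, n_bg, big_k, n_sel))
        rows.append(
            {
                "go_id": go_id,
                "genome_count": big_k,
                "observed": k,
                "expected": expected,
                "representation": representation,
                "raw_p": raw_p,
                "go_description": desc.get(go_id, ""),
            }
        )
    table = pd.DataFrame(rows)
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown correction method {method!r}")
    rejected, corrected, _, _ = multipletests(
        table["raw_p"].to_numpy(), alpha=alpha, method=method
    )
    table["corrected_p"] = corrected
    table["significant"] = table["corrected_p"] < alpha
    table = table.sort_values(["corrected_p", "raw_p"], kind="stable")
    return table.reset_index(drop=True)[ENRICHMENT_COLUMNS]
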