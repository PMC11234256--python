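"""Reference dataset: the Gly1170Ser vs wild-type procollagen-II interactome.

The 26 high-confidence ER interactors of procollagen-II, with their
bait-normalized fold enrichments (Gly1170Ser over wild-type) and
homoscedastic t-test p-values across three biological replicates.  Ships as
a worked example for the multiple-testing stage: running the two-stage BKY
procedure on these 26 p-values at a desired FDR of 10% rejects exactly P4HB
and PLOD2.
"""

from __future__ import annotations

from typing import NamedTuple


class ReferenceInteractor(NamedTuple):
    gene: str
    fold_enrichment: float
    p_value: float


#: (gene symbol, fold enrichment, p-value), in fold-enrichment order.
REFERENCE_INTERACTORS: tuple[ReferenceInteractor, ...] = (
    ReferenceInteractor("PLOD2", 1.95, 0.0014),
    ReferenceInteractor("P4HB", 1.67, 0.0004),
    ReferenceInteractor("P3H1", 1.55, 0.0352),
    ReferenceInteractor("CRTAP", 1.53, 0.0328),
    ReferenceInteractor("FN1", 1.48, 0.0397),
    ReferenceInteractor("FKBP10", 1.45, 0.0450),
    ReferenceInteractor("SERPINH1", 1.45, 0.1294),
    ReferenceInteractor("PPIB", 1.41, 0.0324),
    ReferenceInteractor("P4HA1", 1.41, 0.0947),
    ReferenceInteractor("CNPY2", 1.36, 0.3609),
    ReferenceInteractor("FKBP9", 1.36, 0.1174),
    ReferenceInteractor("PRKCSH", 1.32, 0.1252),
    ReferenceInteractor("P4HA2", 1.31, 0.1772),
    ReferenceInteractor("CALU", 1.31, 0.1904),
    ReferenceInteractor("PLOD1", 1.29, 0.2534),
    ReferenceInteractor("CALR", 1.28, 0.0116),
    ReferenceInteractor("PLOD3", 1.24, 0.3631),
    ReferenceInteractor("COLGALT1", 1.24, 0.3873),
    ReferenceInteractor("CKAP4", 1.17, 0.4509),
    ReferenceInteractor("TXNDC5", 1.14, 0.6372),
    ReferenceInteractor("HSPA5", 1.13, 0.1698),
    ReferenceInteractor("PDIA3", 1.13, 0.2887),
    ReferenceInteractor("HSP90B1", 1.13, 0.2434),
    ReferenceInteractor("LMAN1", 1.11, 0.6354),
    ReferenceInteractor("PDIA4", 1.09, 0.6521),
    ReferenceInteractor("PDIA6", 1.01, 0.9746),
)


def reference_interactors() -> list[tuple[str, float]]:
    """The 26 (gene, p-value) pairs of the reference interactome comparison."""
    return [(r.gene, r.p_value) for r in REFERENCE_INTERACTORS]
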