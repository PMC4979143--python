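"""Published RPKM values for the hooded seal / ferret visual cortex comparison.

These are the reported gene-level RPKM values and fold differences for the
most highly expressed and most differential genes in the visual cortex
transcriptomes of the hooded seal (Cystophora cristata) and the ferret
(Mustela putorius furo).  They serve as small real-data inputs for the
fold-change and ranking operations: the reported fold differences of the
top-expression lists reproduce exactly from the printed RPKM pairs under
the package's signed-fold convention with round-half-up to 2 decimals.

The most-differential list prints RPKM at 1 decimal place while its fold
column was evidently computed from unrounded values upstream, so those
folds are stored for reference but cannot be re-derived from the printed
RPKMs at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReportedGene",
    "SEAL_TOP_EXPRESSED",
    "FERRET_TOP_EXPRESSED",
    "TOP_DIFFERENTIAL",
    "FOLD_REPRODUCIBLE_GENES",
]


@dataclass(frozen=True)
class ReportedGene:
    symbol: str
    seal_rpkm: float
    ferret_rpkm: float
    reported_fold: float


#: Ten most highly expressed genes in the seal visual cortex.
SEAL_TOP_EXPRESSED: tuple[ReportedGene, ...] = (
    ReportedGene("CLU", 3104.57, 777.62, 3.99),
    ReportedGene("PTGDS", 2213.95, 1451.49, 1.53),
    ReportedGene("S100B", 1860.29, 48.98, 37.98),
    ReportedGene("GAPDH", 1413.17, 3728.00, -2.64),
    ReportedGene("GDPD2", 1334.93, 277.95, 4.80),
    ReportedGene("GLUL", 1046.64, 768.49, 1.36),
    ReportedGene("CALM2", 1002.24, 1805.51, -1.80),
    ReportedGene("SPARCL1", 938.95, 536.88, 1.75),
    ReportedGene("ALDOC", 918.67, 906.26, 1.01),
    ReportedGene("PSAP", 883.57, 913.66, -1.03),
)

#: Ten most highly expressed genes in the ferret visual cortex.
FERRET_TOP_EXPRESSED: tuple[ReportedGene, ...] = (
    ReportedGene("GAPDH", 1413.17, 3728.00, -2.64),
    ReportedGene("MTCO2", 245.64, 2266.01, -9.22),
    ReportedGene("LOC101679695", 98.39, 1824.67, -18.55),
    ReportedGene("CALM2", 1002.24, 1805.51, -1.80),
    ReportedGene("CALM1", 480.64, 1802.73, -3.75),
    ReportedGene("PTGDS", 2213.95, 1451.49, 1.53),
    ReportedGene("ATP5B", 541.42, 1166.96, -2.16),
    ReportedGene("LDHB", 453.40, 1127.78, -2.49),
    ReportedGene("MDH1", 544.42, 1055.62, -1.94),
    ReportedGene("RPL26", 289.61, 1040.08, -3.59),
)

#: Genes most overrepresented in the seal cortex (RPKM printed at 1 dp;
#: reported folds computed upstream from unrounded values).
TOP_DIFFERENTIAL: tuple[ReportedGene, ...] = (
    ReportedGene("S100B", 1860.3, 49.0, 37.98),
    ReportedGene("OGN", 288.0, 23.7, 12.14),
    ReportedGene("NEIL2", 51.1, 5.1, 10.11),
    ReportedGene("HSD17B11", 81.3, 12.6, 6.46),
    ReportedGene("B2M", 242.1, 38.7, 6.26),
    ReportedGene("CYP4V2", 86.2, 14.3, 6.05),
    ReportedGene("PON2", 95.9, 17.3, 5.54),
    ReportedGene("BGN", 41.1, 7.7, 5.35),
    ReportedGene("MSN", 60.4, 11.3, 5.33),
    ReportedGene("TM4SF1", 33.4, 6.3, 5.31),
)

#: Symbols whose reported fold difference re-derives exactly from the
#: printed 2-dp RPKM pairs (the top-expression lists above).
FOLD_REPRODUCIBLE_GENES: tuple[str, ...] = (
    "CLU",
    "S100B",
    "GAPDH",
    "MTCO2",
    "LOC101679695",
    "GDPD2",
    "LDHB",
    "ALDOC",
)


def reported_gene(symbol: str) -> ReportedGene:
    """Look up a reported gene from the top-expression lists by symbol."""
    for rec in SEAL_TOP_EXPRESSED + FERRET_TOP_EXPRESSED:
        if rec.symbol == symbol.upper():
            return rec
    raise KeyError(f"{symbol!r} not in the reported top-expression lists")
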