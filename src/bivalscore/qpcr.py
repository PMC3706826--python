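"""Comparative (delta-delta-Ct) relative quantitation and ChIP-qPCR
enrichment.

The classic comparative method assumes 100% amplification efficiency
(doubling per cycle): replicate Cts are averaged on the cycle scale,
delta-Ct = Ct_target - Ct_control per sample, delta-delta-Ct subtracts the
calibrator sample's delta-Ct, and RQ = 2**(-ddCt), so the calibrator's RQ
is identically 1.

ChIP-qPCR enrichment is reported two ways: fold enrichment over the IgG
negative-control immunoprecipitation, 2**(Ct_IgG - Ct_IP), which is the
display convention used for promoter bivalency validation; and percent of
input, where the input Ct is first adjusted for the input fraction
(Ct_input - log2(1/fraction)) and %input = 100 * 2**(adjusted - Ct_IP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd


@dataclass
class EnrichmentInput:
    """Ct values for one amplicon across antibodies plus controls."""

    ct_ip: dict[str, float]
    ct_igg: float
    ct_input: float | None = None
    input_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must lie in (0, 1]")


def relative_quantity(ct_table: pd.DataFrame, target: str, control: str,
                      calibrator: str) -> pd.Series:
    """RQ per sample by the comparative method.

    ``ct_table`` needs columns sample, target, replicate, ct; ``target``
    and ``control`` name the gene-of-interest and endogenous-control assays.
    Replicates are averaged on the Ct scale before exponentiation.
    """
    required = {"sample", "target", "replicate", "ct"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    mean_ct = ct_table.groupby(["sample", "target"])["ct"].mean().unstack()
    for gene in (target, control):
        if gene not in mean_ct.columns or mean_ct[gene].isna().any():
            bad = (mean_ct.index[mean_ct[gene].isna()].tolist()
                   if gene in mean_ct.columns else mean_ct.index.tolist())
            raise ValueError(f"samples missing {gene!r} rows: {bad}")
    if calibrator not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    dct = mean_ct[target] - mean_ct[control]
    ddct = dct - dct[calibrator]
    return (2.0 ** (-ddct)).rename("RQ")


def fold_enrichment(inp: EnrichmentInput, antibody: str) -> float:
    """IgG-normalised fold enrichment, 2**(Ct_IgG - Ct_IP)."""
    if antibody.lower() == "igg":
        return 1.0
    if antibody not in inp.ct_ip:
        raise ValueError(f"unknown antibody {antibody!r}")
    return 2.0 ** (inp.ct_igg - inp.ct_ip[antibody])


def percent_input(inp: EnrichmentInput, antibody: str) -> float:
    """Percent of (fraction-adjusted) chromatin input recovered by the IP."""
    if inp.ct_input is None:
        raise ValueError("ct_input is required for percent-input")
    if antibody not in inp.ct_ip:
        raise ValueError(f"unknown antibody {antibody!r}")
    adjusted = inp.ct_input - math.log2(1.0 / inp.input_fraction)
    return 100.0 * 2.0 ** (adjusted - inp.ct_ip[antibody])


def enrichment_table(inputs: dict[str, EnrichmentInput]) -> pd.DataFrame:
    """Tidy fold-enrichment (and %input where available) per amplicon."""
    rows = []
    for amplicon, inp in inputs.items():
        for ab in inp.ct_ip:
            rows.append({
                "amplicon": amplicon,
                "antibody": ab,
                "fold_enrichment": fold_enrichment(inp, ab),
                "percent_input": (percent_input(inp, ab)
                                  if inp.ct_input is not None else float("nan")),
            })
    return pd.DataFrame(rows)
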