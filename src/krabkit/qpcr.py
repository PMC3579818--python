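"""Relative quantification of RT-qPCR data by the ΔΔCT method.

ΔCT = CT(target) − mean CT(normalizer genes); ΔΔCT = ΔCT(sample) −
ΔCT(reference sample); relative quantity RQ = 2^(−ΔΔCT), so the reference
sample is 1 by construction. Averaging normalizer CTs arithmetically is
equivalent to taking the geometric mean of their quantities. Replicate CT
measurements per (sample, gene) are averaged before any differencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["QpcrResult", "relative_quantity"]


@dataclass(frozen=True)
class QpcrResult:
    sample: str
    target: str
    delta_ct: float
    delta_delta_ct: float
    rq: float


def relative_quantity(
    ct_table: pd.DataFrame,
    target: str,
    normalizers: Sequence[str],
    reference_sample: str,
) -> list[QpcrResult]:
    """Compute per-sample relative quantities of one target gene.

    Parameters
    ----------
    ct_table
        Long-format table with columns sample, gene, ct.
    target
        Gene to quantify.
    normalizers
        Reference genes whose mean CT anchors ΔCT; all must be measured in
        every sample.
    reference_sample
        Sample whose RQ is defined as 1.
    """
    if not list(normalizers):
        raise ValueError("at least one normalizer gene is required")
    need = {"sample", "gene", "ct"}
    if not need <= set(ct_table.columns):
        raise ValueError(f"ct_table needs columns {sorted(need)}")
    mean_ct = ct_table.groupby(["sample", "gene"])["ct"].mean()
    samples = list(dict.fromkeys(ct_table["sample"]))
    if reference_sample not in samples:
        raise ValueError(f"reference sample {reference_sample!r} not in table")

    def norm_ct(sample: str) -> float:
        cts = []
        for g in normalizers:
            if (sample, g) not in mean_ct.index:
                raise ValueError(f"normalizer {g!r} missing in sample {sample!r}")
            cts.append(mean_ct[(sample, g)])
        return float(np.mean(cts))

    def delta(sample: str) -> float | None:
        if (sample, target) not in mean_ct.index:
            return None
        return float(mean_ct[(sample, target)]) - norm_ct(sample)

    ref_delta = delta(reference_sample)
    if ref_delta is None:
        raise ValueError(f"target {target!r} missing in reference sample")

    results = []
    for s in samples:
        d = delta(s)
        if d is None:
            warnings.warn(f"target {target!r} missing in sample {s!r}; RQ omitted")
            continue
        ddct = d - ref_delta
        results.append(
            QpcrResult(
                sample=s,
                target=target,
                delta_ct=d,
                delta_delta_ct=ddct,
                rq=float(2.0 ** (-ddct)),
            )
        )
    return results
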