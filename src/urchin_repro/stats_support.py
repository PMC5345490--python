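"""Cochran's C homogeneity-of-variances statistic.

C = max(s_i^2) / sum(s_i^2) over k groups of common replicate size n.
The statistic lies in [1/k, 1]; values near 1/k indicate homogeneous
variances.  No p-value is computed — the statistic is returned together
with (k, n) so users can consult published critical-value tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .data_model_io import DomainError


class VarianceSet(BaseModel):
    """Group variances (one per cell) with a common replicate count."""

    variances: list[float] = Field(min_length=2)
    n: Optional[int] = Field(default=None, ge=2, description="replicates per group")

    @model_validator(mode="after")
    def _valid(self) -> "VarianceSet":
        if any(v < 0 for v in self.variances):
            raise ValueError("variances must be nonnegative")
        return self


@dataclass(frozen=True)
class CochranResult:
    c: float
    k: int
    n: Optional[int]


def cochran_c(variances: Sequence[float] | VarianceSet, n: Optional[int] = None) -> CochranResult:
    """Compute Cochran's C = max variance / sum of variances."""
    if isinstance(variances, VarianceSet):
        vs, n = variances.variances, variances.n
    else:
        vs = VarianceSet(variances=list(variances), n=n).variances
    total = sum(vs)
    if total <= 0:
        raise DomainError("all group variances are zero; C is undefined")
    return CochranResult(c=max(vs) / total, k=len(vs), n=n)
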