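"""Range-separated (Coulomb-attenuated) hybrid exchange partition.

In a Coulomb-attenuated functional the Hartree-Fock exchange fraction
grows with interelectronic distance r12 as

    w_HF(r12) = alpha + beta * erf(mu * r12),

so the HF weight is alpha at r12 = 0 and alpha + beta at infinity, the
DFT exchange weight being the complement.  CAM-B3LYP uses
alpha = 0.19, beta = 0.46, mu = 0.33 bohr^-1; the B3LYP limit is
alpha = 0.20, beta = 0.  This module evaluates the weights, generates
linear interpolation paths between parameter sets (the diagnostic scan
from CAM-B3LYP toward B3LYP), and emits/decodes QC-input override
stanzas so a scan can be run in an electronic-structure code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf


class RangeSepError(ValueError):
    """Invalid range-separation parameters or arguments."""


@dataclass(frozen=True)
class RangeSepParams:
    """(alpha, beta, mu) triple of a Coulomb-attenuated hybrid.

    alpha : short-range HF-exchange weight, dimensionless, in [0, 1].
    beta : long-range increment; alpha + beta in [0, 1].
    mu : attenuation parameter in bohr^-1, >= 0.
    """

    alpha: float
    beta: float
    mu: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise RangeSepError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 <= self.alpha + self.beta <= 1.0):
            raise RangeSepError(
                f"alpha + beta must be in [0, 1], got {self.alpha + self.beta}"
            )
        if self.mu < 0:
            raise RangeSepError(f"mu must be >= 0 bohr^-1, got {self.mu}")


#: Published defaults.
CAM_B3LYP = RangeSepParams(alpha=0.19, beta=0.46, mu=0.33)
B3LYP = RangeSepParams(alpha=0.20, beta=0.0, mu=0.33)


def hf_weight(r12, params: RangeSepParams):
    """HF-exchange weight alpha + beta*erf(mu*r12) at separation r12 (bohr)."""
    r = np.asarray(r12, dtype=float)
    if np.any(r < 0):
        raise RangeSepError("r12 must be >= 0 bohr")
    w = params.alpha + params.beta * erf(params.mu * r)
    return w if w.ndim else float(w)


def dft_weight(r12, params: RangeSepParams):
    """Complementary DFT-exchange weight, 1 - hf_weight."""
    return 1.0 - hf_weight(r12, params)


def parameter_path(
    start: RangeSepParams, end: RangeSepParams, n_points: int
) -> list[RangeSepParams]:
    """Linear (alpha, beta) interpolation path from *start* to *end*.

    ``n_points`` equally spaced fractions t in [0, 1] including both
    endpoints; mu is held at ``start.mu`` throughout.  Endpoints
    reproduce the inputs exactly.
    """
    if n_points < 2:
        raise RangeSepError(f"n_points must be >= 2, got {n_points}")
    path = []
    for i in range(n_points):
        t = i / (n_points - 1)
        if i == 0:
            a, b = start.alpha, start.beta
        elif i == n_points - 1:
            a, b = end.alpha, end.beta
        else:
            a = (1 - t) * start.alpha + t * end.alpha
            b = (1 - t) * start.beta + t * end.beta
        path.append(RangeSepParams(alpha=a, beta=b, mu=start.mu))
    return path


def path_to_frame(path: list[RangeSepParams]) -> pd.DataFrame:
    """Tabulate a parameter path; points are 1-indexed to match (a)-(e) labels."""
    n = len(path)
    return pd.DataFrame(
        {
            "point": np.arange(1, n + 1),
            "t": np.arange(n) / (n - 1) if n > 1 else [0.0],
            "alpha": [p.alpha for p in path],
            "beta": [p.beta for p in path],
            "mu": [p.mu for p in path],
        }
    )


# --- override stanza -------------------------------------------------------
#
# Stanza layout (documented, bit-exact):
#   line 1: "! rsh alpha=<repr> beta=<repr> mu=<repr>" — full-precision
#           machine comment, the authoritative decode source;
#   lines 2-4: IOp-style integer fields, each parameter scaled by 1e5
#           and zero-padded to 7 digits (5-decimal granularity, the
#           convention of mainstream QC input overrides).
_STANZA_RE = re.compile(
    r"^! rsh alpha=(?P<alpha>\S+) beta=(?P<beta>\S+) mu=(?P<mu>\S+)$", re.M
)


def emit_overrides(params: RangeSepParams) -> str:
    """Render a QC-input override stanza for the given parameters."""
    # dataclass validation already ran; re-raise for mutated instances
    RangeSepParams(params.alpha, params.beta, params.mu)
    lines = [
        f"! rsh alpha={params.alpha!r} beta={params.beta!r} mu={params.mu!r}",
        f"IOp(3/107={round(params.mu * 1e5):07d})",
        f"IOp(3/119={round(params.alpha * 1e5):07d})",
        f"IOp(3/120={round((params.alpha + params.beta) * 1e5):07d})",
    ]
    return "\n".join(lines) + "\n"


def decode_overrides(stanza: str) -> RangeSepParams:
    """Invert :func:`emit_overrides`; exact round-trip via the comment line."""
    m = _STANZA_RE.search(stanza)
    if m is None:
        raise RangeSepError("stanza lacks the '! rsh ...' parameter comment line")
    return RangeSepParams(
        alpha=float(m.group("alpha")),
        beta=float(m.group("beta")),
        mu=float(m.group("mu")),
    )
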