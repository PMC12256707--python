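"""Small shared numerics: clamped logit/expit and seed fan-out."""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit
from scipy.special import logit as _logit

#: probabilities are clamped into [RISK_EPS, 1 - RISK_EPS] before logit
RISK_EPS = 1e-12


def expit(x):
    return _expit(np.asarray(x, dtype=float))


def clamped_logit(p):
    """Log-odds of p with p clamped away from {0, 1} so the result is finite."""
    p = np.clip(np.asarray(p, dtype=float), RISK_EPS, 1.0 - RISK_EPS)
    return _logit(p)


def spawn_seed(seed: int, offset: int) -> int:
    """Derive a stream-specific seed from a global one (stays below 2**31)."""
    return int((int(seed) * 1_000_003 + offset) % (2**31 - 1))
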