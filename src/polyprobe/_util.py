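"""Small shared helpers: rounding conventions and file headers."""
from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimal places.

    Python's builtin ``round`` is banker's rounding; reported percentages and
    fold enrichments use the conventional half-up rule instead (10.5% -> 11%).
    Operates on the shortest decimal repr of the float, so 0.575 stored as
    0.57499... rounds by its printed digits.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(k: int, n: int) -> int:
    """Integer percentage of k out of n, rounded half-up."""
    if n <= 0:
        raise ValueError("percent denominator must be positive")
    return int(round_half_up(100.0 * k / n, 0))


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
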