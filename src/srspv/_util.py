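"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, digits: int = 1) -> float:
    """Round half away from zero at a fixed number of decimals.

    Matches the presentation convention of the reference tables (20.35
    rounds to 20.4), unlike Python's banker's rounding.
    """
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def spawn_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed (< 2**31) from one master seed."""
    import hashlib

    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
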