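"""Small shared helpers: seed mixing and stable content hashing."""

from __future__ import annotations

import hashlib
import json

_MASK64 = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15


def splitmix64(*values: int) -> int:
    """Mix one or more integers into a reproducible sub-seed.

    Chains the splitmix64 finalizer over the inputs so that runs derived
    from (seed, index) pairs are statistically independent yet fully
    reproducible.  The result is truncated to 31 bits so it is accepted
    by every downstream RNG seed parameter.
    """
    state = 0
    for v in values:
        state = (state + int(v) + _GOLDEN) & _MASK64
        z = state
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
        state = z ^ (z >> 31)
    return state & 0x7FFFFFFF


def stable_hash(obj) -> str:
    """SHA-256 of a canonical JSON rendering of ``obj`` (hex digest).

    Floats are rendered with repr via JSON, which is platform-stable for
    IEEE doubles; dict keys are sorted so insertion order never matters.
    """
    payload = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(payload.encode()).hexdigest()
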