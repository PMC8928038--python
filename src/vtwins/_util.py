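"""Small shared helpers: seed derivation and p-value formatting."""

from __future__ import annotations

import hashlib

#: Display floor for p-values, following the convention of reporting
#: anything below double machine epsilon as an inequality.
P_FLOOR = 2.2e-16


def derive_seed(master_seed: int, label: str) -> int:
    """Derive a stage-specific seed from a master seed.

    Stages draw from independent streams keyed by name, so editing one
    stage's configuration does not perturb the randomness of another.
    The result is always in [0, 2**31).
    """
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def format_p(p: float) -> str:
    """Render a p-value, flooring tiny values at ``< 2.20e-16``."""
    if p < P_FLOOR:
        return "< 2.20e-16"
    return f"{p:.3g}"
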