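"""Deterministic derivation of per-stage child seeds from one master seed.

Every stochastic stage (simulation, permutation nulls, bootstraps) receives
its own child seed computed from the master seed plus a stage label, so that
adding or reordering stages never shifts the random stream of another stage.
The scheme is a SHA-256 hash of ``"<master>|<label>|<label>|..."`` truncated
to 31 bits, which keeps seeds portable across platforms and RNG back ends.
"""

from __future__ import annotations

import hashlib


def child_seed(master: int, *labels: object) -> int:
    """Derive a deterministic child seed below 2**31 from a master seed.

    Parameters
    ----------
    master:
        The user-facing master seed.
    labels:
        Arbitrary hashable stage labels, e.g. ``("network", "tn1")``.
    """
    key = "|".join([str(int(master)), *[str(l) for l in labels]])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
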