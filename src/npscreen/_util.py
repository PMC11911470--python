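"""Shared plumbing: errors, seed derivation, p-value flooring."""

from __future__ import annotations

import zlib

import numpy as np

#: floor applied to p-values before -log10 so ranking statistics stay finite
P_FLOOR = 1e-300

#: ceiling applied before normal-quantile transforms (keeps z finite)
P_CEILING = 1.0 - 1e-16


class ConfigurationError(ValueError):
    """A configuration value or schema mapping is unusable."""


class InputError(ValueError):
    """An input file or in-memory input violates the interface contract."""


def derived_seed(seed: int, *tokens) -> int:
    """Derive a stable sub-stream seed from a top-level seed and string tokens.

    Independent stages get independent streams keyed by name, so adding a
    dataset to a run does not perturb the randomness of unrelated stages.
    The result is kept below 2**31.
    """
    tag = "/".join(str(t) for t in tokens)
    mix = zlib.crc32(tag.encode("utf-8"))
    return int((int(seed) ^ (mix * 2654435761)) % (2**31 - 1))


def neglog10(p, floor: float = P_FLOOR):
    """-log10(p) with flooring; accepts scalars or arrays."""
    return -np.log10(np.maximum(p, floor))
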