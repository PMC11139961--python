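"""Electrode montages.

The 19-channel international 10-20 montage is the default layout for
resting-state clinical EEG and the one all default configurations assume.
Channel NAMES are the external interface everywhere in this package; masks
and column indices are always 0-based positions into an ordered montage list.
"""

from __future__ import annotations

#: Ordered 19-channel 10-20 montage (frontal to occipital).
STANDARD_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Canonical EEG rhythm bands in Hz (delta, theta, alpha, beta, gamma).
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 64.0),
}


def validate_montage(montage: "list[str] | tuple[str, ...]") -> tuple[str, ...]:
    """Return the montage as a tuple, checking it is non-empty with unique names."""
    names = tuple(montage)
    if not names:
        raise ValueError("montage must contain at least one channel name")
    if len(set(names)) != len(names):
        raise ValueError("montage channel names must be unique")
    return names
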