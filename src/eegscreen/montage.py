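"""The 19-channel international 10-20 montage and its spatial adjacency.

Channel order is frozen: every feature name, coherence pair enumeration and
output table in the package uses this order. Legacy temporal/posterior names
(T3/T4/T5/T6) are canonical; the modern equivalents (T7/T8/P7/P8) are
accepted as aliases on input.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

CHANNEL_INDEX: dict[str, int] = {ch: i for i, ch in enumerate(CHANNELS)}

#: modern 10-10 names -> legacy 10-20 names used throughout
ALIASES: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

_CANONICAL_LOWER = {ch.lower(): ch for ch in CHANNELS}
_ALIAS_LOWER = {a.lower(): c for a, c in ALIASES.items()}

# Spatial adjacency on the scalp, derived once from published standard 10-20
# spherical coordinates: two electrodes are neighbors iff their angular
# separation (from the head center) is <= 52 degrees.  The table is frozen
# here; it is symmetric and every channel has at least 3 neighbors.
NEIGHBORS: dict[str, frozenset[str]] = {
    "Fp1": frozenset({"F3", "F7", "Fp2"}),
    "Fp2": frozenset({"F4", "F8", "Fp1"}),
    "F7": frozenset({"F3", "Fp1", "T3"}),
    "F3": frozenset({"C3", "F7", "Fp1", "Fz"}),
    "Fz": frozenset({"Cz", "F3", "F4"}),
    "F4": frozenset({"C4", "F8", "Fp2", "Fz"}),
    "F8": frozenset({"F4", "Fp2", "T4"}),
    "T3": frozenset({"C3", "F7", "T5"}),
    "C3": frozenset({"Cz", "F3", "P3", "T3"}),
    "Cz": frozenset({"C3", "C4", "Fz", "Pz"}),
    "C4": frozenset({"Cz", "F4", "P4", "T4"}),
    "T4": frozenset({"C4", "F8", "T6"}),
    "T5": frozenset({"O1", "P3", "T3"}),
    "P3": frozenset({"C3", "O1", "Pz", "T5"}),
    "Pz": frozenset({"Cz", "O1", "O2", "P3", "P4"}),
    "P4": frozenset({"C4", "O2", "Pz", "T6"}),
    "T6": frozenset({"O2", "P4", "T4"}),
    "O1": frozenset({"O2", "P3", "Pz", "T5"}),
    "O2": frozenset({"O1", "P4", "Pz", "T6"}),
}


def normalize_label(label: str) -> str | None:
    """Map a channel label to its canonical montage name.

    Matching is case-insensitive and accepts the modern T7/T8/P7/P8 aliases.
    Returns ``None`` for labels outside the 19-channel montage.
    """
    key = label.strip().lower()
    if key in _CANONICAL_LOWER:
        return _CANONICAL_LOWER[key]
    if key in _ALIAS_LOWER:
        return _ALIAS_LOWER[key]
    return None


def montage_neighbors(channel: str) -> frozenset[str]:
    """Return the fixed spatial-adjacency set of a montage channel.

    Raises ``KeyError`` for labels outside the montage.
    """
    canonical = normalize_label(channel)
    if canonical is None:
        raise KeyError(f"unknown 10-20 channel label: {channel!r}")
    return NEIGHBORS[canonical]


def sort_pair(ch_a: str, ch_b: str) -> tuple[str, str]:
    """Order a channel pair by montage position (used for coherence names)."""
    if CHANNEL_INDEX[ch_a] <= CHANNEL_INDEX[ch_b]:
        return ch_a, ch_b
    return ch_b, ch_a
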