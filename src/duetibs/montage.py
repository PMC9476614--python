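"""Electrode montage and regions of interest.

The 29-channel layout follows the extended 10-20 system cap used in dual-EEG
duet recordings.  Inter-brain metrics here are always computed between
*homologous* electrodes of the two players (C3-C3, C4-C4, ...), so a region of
interest (ROI) is simply a subset of channel names applied to both players.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "CZ", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "PZ", "P4", "P8",
    "O1", "OZ", "O2",
)

#: Right-posterior ROI repeatedly implicated in interactional synchrony.
RP_ROI: tuple[str, ...] = ("C4", "CP2", "CP6", "P4", "P8")
#: Left-posterior homolog of :data:`RP_ROI`.
LP_ROI: tuple[str, ...] = ("C3", "CP1", "CP5", "P3", "P7")

ROIS: dict[str, tuple[str, ...]] = {
    "GLOBAL": CHANNELS,
    "RP": RP_ROI,
    "LP": LP_ROI,
}


def roi_channels(roi: str) -> tuple[str, ...]:
    """Return the channel names of a named ROI (``GLOBAL``, ``RP`` or ``LP``)."""
    try:
        return ROIS[roi.upper()]
    except KeyError:
        raise ValueError(
            f"unknown ROI {roi!r}; available: {sorted(ROIS)}"
        ) from None


def roi_indices(roi: str, ch_names) -> list[int]:
    """Indices of a ROI's channels within ``ch_names``.

    Raises ``ValueError`` if any ROI channel is missing from the montage
    actually present in the data.
    """
    names = [c.upper() for c in ch_names]
    idx = []
    for ch in roi_channels(roi):
        try:
            idx.append(names.index(ch))
        except ValueError:
            raise ValueError(f"ROI {roi!r} channel {ch} not in data montage") from None
    return idx
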