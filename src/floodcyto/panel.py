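"""Staining panel definition for the neutrophil phenotyping pipeline.

The panel models a 12-parameter acquisition: forward/side scatter plus ten
fluorescence markers covering activation/degranulation (CD35, CD66b, CD11b,
CBRM1/5), maturity and adhesion (CD16, CD62L, CD49d), inhibitory signalling
(LAIR-1), Fc receptor (CD64) and a monocyte exclusion channel (CD14).
"""

from __future__ import annotations

from dataclasses import dataclass, field


SCATTER_CHANNELS = ("FSC", "SSC")

#: The ten fluorescence markers of the staining combination, in panel order.
FLUORESCENCE_MARKERS = (
    "CD35",
    "CD64",
    "CBRM1/5",
    "CD11b",
    "LAIR-1",
    "CD14",
    "CD16",
    "CD62L",
    "CD49d",
    "CD66b",
)

#: Markers whose median fluorescence intensity is tracked over the cohort
#: time course (the six activation/maturity markers reported per time point).
MFI_MARKERS = ("CD35", "CD66b", "CD11b", "CBRM1/5", "CD49d", "LAIR-1")


@dataclass(frozen=True)
class PanelDef:
    """Ordered channel list with a scatter/fluorescence role per channel.

    Parameters
    ----------
    channels
        Channel names in acquisition order. Names must be unique.
    roles
        Mapping from channel name to ``"scatter"`` or ``"fluorescence"``.
    """

    channels: tuple[str, ...]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        roles = dict(self.roles)
        for ch in self.channels:
            roles.setdefault(
                ch, "scatter" if ch in SCATTER_CHANNELS else "fluorescence"
            )
        object.__setattr__(self, "roles", roles)

    @property
    def fluorescence_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if self.roles[c] == "fluorescence")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel!r} not in panel") from None

    def require(self, *channels: str) -> None:
        """Raise :class:`PanelError` if any named channel is absent."""
        missing = [c for c in channels if c not in self.channels]
        if missing:
            raise PanelError(f"panel is missing required channel(s): {missing}")


class PanelError(KeyError):
    """A required channel is absent from the panel."""


def default_panel() -> PanelDef:
    """The full 12-channel panel (FSC, SSC + ten markers)."""
    return PanelDef(channels=SCATTER_CHANNELS + FLUORESCENCE_MARKERS)
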