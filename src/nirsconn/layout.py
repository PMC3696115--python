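"""Channel-to-region registry for the optical-topography probe set.

The instrument measures 94 channels from four bilateral probe pads placed
over the frontal, temporal, parietal and occipital regions.  The exact
channel geometry is instrument- and cap-specific, so the registry shipped
here is an approximate default — channels are split evenly across the eight
region labels — and can be replaced wholesale by loading a layout CSV.

Channels are numbered 1-based externally, matching instrument convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REGIONS = (
    "frontal-L",
    "frontal-R",
    "temporal-L",
    "temporal-R",
    "parietal-L",
    "parietal-R",
    "occipital-L",
    "occipital-R",
)


@dataclass(frozen=True)
class ChannelLayout:
    """Assignment of measurement channels to cortical region labels.

    Parameters
    ----------
    n_channels:
        Total number of measurement channels (default 94).
    channel_region:
        Mapping from 1-based channel index to a region label in
        :data:`REGIONS`.
    homotopic_pairs:
        ``(left_channel, right_channel)`` tuples linking mirror-region
        channels.
    """

    n_channels: int
    channel_region: dict[int, str] = field(repr=False)
    homotopic_pairs: tuple[tuple[int, int], ...] = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.channel_region) != set(range(1, self.n_channels + 1)):
            raise ValueError("channel_region must cover channels 1..n_channels exactly")
        bad = {r for r in self.channel_region.values()} - set(REGIONS)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        for left, right in self.homotopic_pairs:
            lr = self.channel_region[left]
            rr = self.channel_region[right]
            if lr[:-2] != rr[:-2] or lr[-1] != "L" or rr[-1] != "R":
                raise ValueError(f"pair ({left}, {right}) does not link mirror regions")

    def channels_in(self, region: str) -> list[int]:
        return [ch for ch, r in sorted(self.channel_region.items()) if r == region]

    def homotopic_partner(self, channel: int) -> int | None:
        for left, right in self.homotopic_pairs:
            if channel == left:
                return right
            if channel == right:
                return left
        return None

    def to_frame(self) -> pd.DataFrame:
        partner = {ch: self.homotopic_partner(ch) for ch in self.channel_region}
        return pd.DataFrame(
            {
                "channel": sorted(self.channel_region),
                "region": [self.channel_region[c] for c in sorted(self.channel_region)],
                "homotopic_partner": [partner[c] for c in sorted(self.channel_region)],
            }
        )


def default_layout(n_channels: int = 94) -> ChannelLayout:
    """Build the default even-split registry.

    Channels are assigned contiguously to the eight region labels in the
    order of :data:`REGIONS`; any remainder after the even split is given to
    the anterior regions first so that left/right counts stay balanced.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels (one per region)")
    base, rem = divmod(n_channels, 8)
    counts = [base] * 8
    # hand out the remainder two at a time to keep L/R balanced per lobe
    pair_idx = 0
    while rem >= 2:
        counts[2 * pair_idx] += 1
        counts[2 * pair_idx + 1] += 1
        rem -= 2
        pair_idx += 1
    if rem:  # odd channel count: last region takes the orphan
        counts[-1] += 1
    channel_region: dict[int, str] = {}
    ch = 1
    for region, count in zip(REGIONS, counts):
        for _ in range(count):
            channel_region[ch] = region
            ch += 1
    pairs: list[tuple[int, int]] = []
    for li in range(0, 8, 2):
        left = [c for c, r in sorted(channel_region.items()) if r == REGIONS[li]]
        right = [c for c, r in sorted(channel_region.items()) if r == REGIONS[li + 1]]
        pairs.extend(zip(left, right))
    return ChannelLayout(
        n_channels=n_channels,
        channel_region=channel_region,
        homotopic_pairs=tuple(pairs),
    )


def read_layout(path) -> ChannelLayout:
    """Load a layout registry from CSV (columns: channel, region, homotopic_partner)."""
    df = pd.read_csv(path)
    required = {"channel", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"layout file missing columns: {sorted(missing)}")
    channel_region = {int(r.channel): str(r.region) for r in df.itertuples()}
    pairs = []
    if "homotopic_partner" in df.columns:
        seen = set()
        for r in df.itertuples():
            if pd.isna(r.homotopic_partner):
                continue
            ch, partner = int(r.channel), int(r.homotopic_partner)
            key = (min(ch, partner), max(ch, partner))
            if key in seen:
                continue
            seen.add(key)
            if channel_region[ch].endswith("-L"):
                pairs.append((ch, partner))
            else:
                pairs.append((partner, ch))
    return ChannelLayout(
        n_channels=len(channel_region),
        channel_region=channel_region,
        homotopic_pairs=tuple(sorted(pairs)),
    )


def write_layout(layout: ChannelLayout, path) -> None:
    layout.to_frame().to_csv(path, index=False)
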