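"""Atlas region-to-subnetwork mapping.

Every cortical region is assigned to exactly one of the seven canonical
resting-state subnetworks (visual, somatomotor, dorsal attention, ventral
attention, limbic, fronto-parietal, default mode). The fronto-parietal
network (FPN) mask is the one used for subnetwork-averaged centrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical seven-network labels, in conventional order.
SEVEN_NETWORKS: tuple[str, ...] = ("VN", "SMN", "DAN", "VAN", "LMN", "FPN", "DMN")


@dataclass(frozen=True)
class AtlasMapping:
    """Maps each region index to a (name, subnetwork) pair.

    Parameters
    ----------
    region_names
        Ordered region labels; position is the 0-based region index shared by
        every connectivity matrix and time series in an analysis.
    subnetworks
        Subnetwork label per region, same order.
    """

    region_names: tuple[str, ...]
    subnetworks: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "region_names", tuple(self.region_names))
        object.__setattr__(self, "subnetworks", tuple(self.subnetworks))
        if len(self.region_names) != len(self.subnetworks):
            raise ValueError(
                f"{len(self.region_names)} region names but "
                f"{len(self.subnetworks)} subnetwork labels"
            )
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("duplicate region names in atlas mapping")

    def __len__(self) -> int:
        return len(self.region_names)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def labels(self) -> tuple[str, ...]:
        """Distinct subnetwork labels present, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.subnetworks:
            seen.setdefault(s)
        return tuple(seen)

    def mask(self, label: str) -> np.ndarray:
        """Boolean mask selecting the regions of one subnetwork."""
        if label not in self.subnetworks:
            raise KeyError(f"subnetwork {label!r} not present in atlas mapping")
        return np.asarray([s == label for s in self.subnetworks], dtype=bool)

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.mask(label))

    @property
    def fpn_mask(self) -> np.ndarray:
        return self.mask("FPN")

    def subset(self, keep: np.ndarray) -> "AtlasMapping":
        """Mapping restricted to the regions selected by ``keep`` (bool or index)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return AtlasMapping(
            tuple(self.region_names[i] for i in keep),
            tuple(self.subnetworks[i] for i in keep),
        )


def balanced_partition(n_regions: int, labels: tuple[str, ...] = SEVEN_NETWORKS) -> dict[str, int]:
    """Partition ``n_regions`` as evenly as possible over the given labels."""
    if n_regions < 10:
        raise ValueError(
            f"n_regions={n_regions} is too small for a {len(labels)}-module "
            "partition; need at least 10"
        )
    base, extra = divmod(n_regions, len(labels))
    return {lab: base + (1 if k < extra else 0) for k, lab in enumerate(labels)}


def make_atlas(
    n_regions: int,
    subnetwork_sizes: dict[str, int] | None = None,
    field_prefix: str = "R",
) -> AtlasMapping:
    """Build an atlas mapping with contiguous subnetwork blocks.

    ``subnetwork_sizes`` must partition ``n_regions`` exactly over seven
    labels including ``FPN``; by default the regions are split as evenly as
    possible.
    """
    sizes = subnetwork_sizes or balanced_partition(n_regions)
    if set(sizes) != set(SEVEN_NETWORKS):
        raise ValueError(
            f"subnetwork_sizes labels {sorted(sizes)} must be exactly "
            f"{sorted(SEVEN_NETWORKS)}"
        )
    if sum(sizes.values()) != n_regions:
        raise ValueError(
            f"subnetwork sizes sum to {sum(sizes.values())}, expected {n_regions}"
        )
    if n_regions < 10:
        raise ValueError(f"n_regions={n_regions} too small; need at least 10")
    names: list[str] = []
    nets: list[str] = []
    for lab in SEVEN_NETWORKS:
        for k in range(sizes[lab]):
            names.append(f"{field_prefix}{len(names):03d}_{lab}{k}")
            nets.append(lab)
    return AtlasMapping(tuple(names), tuple(nets))
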