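"""Region tables: the mapping from parcel to resting-state network.

A cohort's node set is a fixed parcellation (by default 90 regions, the
size of the AAL atlas) partitioned into five resting-state networks (RSNs):
somatomotor (SMN), visual (VN), attention (AN), default mode (DMN) and
limbic/subcortical (LSN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError

#: Canonical RSN label order used throughout the package.
RSN_NAMES: tuple[str, ...] = ("SMN", "VN", "AN", "DMN", "LSN")


@dataclass(frozen=True)
class RegionTable:
    """Immutable region -> RSN assignment.

    Parameters
    ----------
    region_index
        1-based, unique, contiguous region indices (1..N).
    region_name
        Short AAL-style label per region.
    rsn
        RSN label per region; every label must be one of :data:`RSN_NAMES`
        and at least two distinct labels must occur.
    """

    region_index: np.ndarray
    region_name: tuple[str, ...]
    rsn: tuple[str, ...]
    _members: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        idx = np.asarray(self.region_index, dtype=int)
        object.__setattr__(self, "region_index", idx)
        object.__setattr__(self, "region_name", tuple(self.region_name))
        object.__setattr__(self, "rsn", tuple(self.rsn))
        n = idx.size
        if not (len(self.region_name) == len(self.rsn) == n):
            raise InvalidInputError("region table columns have unequal lengths")
        if not np.array_equal(np.sort(idx), np.arange(1, n + 1)):
            raise InvalidInputError(
                "region_index must be unique and contiguous from 1 to N"
            )
        unknown = set(self.rsn) - set(RSN_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown RSN labels: {sorted(unknown)}")
        if len(set(self.rsn)) < 2:
            raise InvalidInputError("at least 2 distinct RSN labels required")
        members = {}
        order = np.argsort(idx)
        for pos in order:
            members.setdefault(self.rsn[pos], []).append(int(idx[pos]) - 1)
        object.__setattr__(
            self, "_members", {k: np.array(v, dtype=int) for k, v in members.items()}
        )

    @property
    def n_regions(self) -> int:
        return self.region_index.size

    @property
    def rsn_labels(self) -> tuple[str, ...]:
        """RSN labels present, in canonical order."""
        present = set(self.rsn)
        return tuple(r for r in RSN_NAMES if r in present)

    def members(self, rsn: str) -> np.ndarray:
        """0-based region positions belonging to `rsn` (sorted)."""
        if rsn not in self._members:
            raise InvalidInputError(f"RSN {rsn!r} not present in region table")
        return self._members[rsn]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_index": self.region_index,
                "region_name": list(self.region_name),
                "rsn": list(self.rsn),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegionTable":
        required = {"region_index", "region_name", "rsn"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"region table missing columns: {sorted(missing)}")
        return cls(
            region_index=df["region_index"].to_numpy(dtype=int),
            region_name=tuple(str(s) for s in df["region_name"]),
            rsn=tuple(str(s) for s in df["rsn"]),
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RegionTable":
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"cannot read region table {path}: {exc}") from exc
        return cls.from_dataframe(df)
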