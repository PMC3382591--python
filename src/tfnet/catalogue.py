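"""TF -> target regulation catalogue.

A catalogue is a list of (tf, target[, sign]) entries describing
experimentally established regulations. Enrichment scoring ignores the
sign (sign-less mode); the sign column is carried through for provenance
only.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .errors import ContractError, UnknownIdentifierError


class RegulationCatalogue:
    """Immutable TF->target edge list with set-based views.

    Parameters
    ----------
    entries:
        DataFrame with columns ``tf`` and ``target`` (optional ``sign``),
        or any iterable of (tf, target) / (tf, target, sign) tuples.
        Duplicate (tf, target) pairs are rejected.
    """

    def __init__(self, entries) -> None:
        if not isinstance(entries, pd.DataFrame):
            entries = pd.DataFrame(list(entries))
            entries.columns = ["tf", "target", "sign"][: entries.shape[1]]
        if not {"tf", "target"}.issubset(entries.columns):
            raise ContractError("catalogue needs 'tf' and 'target' columns")
        if "sign" not in entries.columns:
            entries = entries.assign(sign="")
        dup = entries.duplicated(subset=["tf", "target"])
        if dup.any():
            pairs = entries.loc[dup, ["tf", "target"]].itertuples(index=False)
            raise ContractError(
                "duplicate catalogue entries: "
                + ", ".join(f"{t}->{g}" for t, g in list(pairs)[:5])
            )
        if entries.empty:
            raise ContractError("catalogue is empty")
        self._entries = entries.reset_index(drop=True)
        self._targets_of: dict[str, frozenset[str]] = {
            tf: frozenset(grp["target"])
            for tf, grp in entries.groupby("tf", sort=True)
        }

    @property
    def entries(self) -> pd.DataFrame:
        return self._entries.copy()

    @property
    def tfs(self) -> frozenset[str]:
        """All TFs with at least one target (every TF, by construction)."""
        return frozenset(self._targets_of)

    @property
    def targets(self) -> frozenset[str]:
        """The union of all target genes."""
        return frozenset(self._entries["target"])

    def targets_of(self, tf: str) -> frozenset[str]:
        try:
            return self._targets_of[tf]
        except KeyError:
            raise UnknownIdentifierError(f"TF {tf!r} not in catalogue") from None

    def targets_of_many(self, tfs: Iterable[str]) -> frozenset[str]:
        """Deduplicated union of the target sets of ``tfs``."""
        out: set[str] = set()
        for tf in tfs:
            out |= self.targets_of(tf)
        return frozenset(out)

    def as_mapping(self) -> Mapping[str, frozenset[str]]:
        return dict(self._targets_of)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RegulationCatalogue({len(self)} regulations, "
            f"{len(self.tfs)} TFs, {len(self.targets)} targets)"
        )
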