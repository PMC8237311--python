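"""Shared result container for every variable-selection method."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STATUS_SELECTED = "selected"
STATUS_REJECTED = "rejected"
STATUS_TENTATIVE = "tentative"
_VALID_STATUS = {STATUS_SELECTED, STATUS_REJECTED, STATUS_TENTATIVE}


@dataclass
class SelectionResult:
    """Outcome of one variable-selection run.

    Attributes
    ----------
    method : str
        Selector label (``"lasso"``, ``"gapls"``, ``"gasvr"``, ``"boruta"``,
        ``"rboruta"``).
    selected : ndarray of int
        Sorted indices of selected columns.
    status : ndarray of str
        Per-column status, one of ``selected`` / ``rejected`` /
        ``tentative``; exactly the columns with status ``selected`` appear
        in ``selected``.
    meta : dict
        Method-specific diagnostics (chosen penalty, CV r2, hit counts,
        decoded SVR parameters, seed, ...), JSON-serializable.
    names : list of str, optional
        Column names aligned with ``status``.
    """

    method: str
    selected: np.ndarray
    status: np.ndarray
    meta: dict = field(default_factory=dict)
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        self.status = np.asarray(self.status, dtype=object)
        bad = set(self.status) - _VALID_STATUS
        if bad:
            raise ValueError(f"invalid statuses: {bad}")
        from_status = np.flatnonzero(self.status == STATUS_SELECTED)
        if not np.array_equal(np.sort(self.selected), from_status):
            raise ValueError("selected indices inconsistent with status vector")
        self.selected = np.sort(self.selected)
        if self.names is not None and len(self.names) != len(self.status):
            raise ValueError("names length must match status length")

    @property
    def n_vars(self) -> int:
        return len(self.status)

    @property
    def support(self) -> np.ndarray:
        """Boolean mask over columns, True where selected."""
        mask = np.zeros(self.n_vars, dtype=bool)
        mask[self.selected] = True
        return mask

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": self.selected.tolist(),
            "selected_names": (
                [self.names[i] for i in self.selected] if self.names else None
            ),
            "status": list(self.status),
            "meta": self.meta,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            method=d["method"],
            selected=np.asarray(d["selected"], dtype=int),
            status=np.asarray(d["status"], dtype=object),
            meta=d.get("meta", {}),
            names=d.get("selected_names") and None or d.get("names"),
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def result_from_support(
    method: str,
    support: np.ndarray,
    meta: dict | None = None,
    names: list[str] | None = None,
    tentative: np.ndarray | None = None,
) -> SelectionResult:
    """Build a SelectionResult from a boolean support mask."""
    support = np.asarray(support, dtype=bool)
    status = np.where(support, STATUS_SELECTED, STATUS_REJECTED).astype(object)
    if tentative is not None:
        status[np.asarray(tentative, dtype=bool) & ~support] = STATUS_TENTATIVE
    return SelectionResult(
        method=method,
        selected=np.flatnonzero(support),
        status=status,
        meta=meta or {},
        names=names,
    )
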