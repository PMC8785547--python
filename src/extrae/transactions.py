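"""Transaction datasets: one record per patient listing co-occurring medical problems.

The mining input is a plain market-basket corpus — each transaction is the
set of problem identifiers recorded for one patient.  Two on-disk layouts
are supported: *basket* text (one delimited transaction per line) and *long*
CSV (one row per patient/problem pair, grouped by a patient-id column).
Items are opaque strings; no terminology mapping is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "TransactionDataset",
    "read_basket",
    "write_basket",
    "read_long_csv",
    "normalize_items",
]

_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class TransactionDataset:
    """An immutable collection of item-set transactions.

    Parameters
    ----------
    transactions : tuple of frozenset of str
        One non-empty item set per patient record.  Duplicate items within
        a record collapse under set semantics.
    """

    transactions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.transactions) < 1:
            raise ValueError("dataset must contain at least one transaction")
        for i, t in enumerate(self.transactions):
            if not isinstance(t, frozenset):
                object.__setattr__(
                    self,
                    "transactions",
                    tuple(frozenset(x) for x in self.transactions),
                )
                t = self.transactions[i]
            if not t:
                raise ValueError(f"transaction {i} is empty")

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)

    @property
    def vocabulary(self) -> frozenset[str]:
        vocab: set[str] = set()
        for t in self.transactions:
            vocab |= t
        return frozenset(vocab)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.transactions)

    def __len__(self) -> int:
        return len(self.transactions)

    @classmethod
    def from_iterable(cls, transactions: Iterable[Iterable[str]]) -> "TransactionDataset":
        return cls(tuple(frozenset(t) for t in transactions))


def read_basket(path: str | Path, delimiter: str = ",") -> TransactionDataset:
    """Read a basket-format file: one transaction per non-blank line.

    Item tokens are stripped of surrounding whitespace; duplicates within a
    line collapse to one.  Raises ``ValueError`` on an empty file or on a
    line with no non-empty tokens.
    """
    text = Path(path).read_text(encoding="utf-8")
    transactions: list[frozenset[str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        items = frozenset(tok.strip() for tok in line.split(delimiter) if tok.strip())
        if not items:
            raise ValueError(f"{path}:{lineno}: line holds no items")
        transactions.append(items)
    if not transactions:
        raise ValueError(f"{path}: no transactions")
    return TransactionDataset(tuple(transactions))


def write_basket(ds: TransactionDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write basket format; items within a line are sorted for reproducibility."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in ds.transactions:
            fh.write(delimiter.join(sorted(t)) + "\n")


def read_long_csv(
    path: str | Path, id_column: str = "patient_id", item_column: str = "item"
) -> TransactionDataset:
    """Read long-format CSV: rows grouped by ``id_column``, one transaction per id.

    Transaction order follows first appearance of each id.
    """
    df = pd.read_csv(path, dtype=str)
    for col in (id_column, item_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    grouped = df.groupby(id_column, sort=False)[item_column]
    return TransactionDataset.from_iterable(
        frozenset(str(v).strip() for v in values) for _, values in grouped
    )


def normalize_items(ds: TransactionDataset) -> TransactionDataset:
    """Casefold items and collapse internal whitespace; idempotent.

    This deliberately implements only spelling-agnostic cleanup — clinical
    text normalization is out of scope and the downstream method does not
    depend on item spelling.
    """

    def norm(item: str) -> str:
        return _WS.sub(" ", item.strip()).casefold()

    return TransactionDataset.from_iterable(
        frozenset(norm(i) for i in t) for t in ds.transactions
    )
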