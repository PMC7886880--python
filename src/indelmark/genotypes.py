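"""Lines x markers genotype matrix of co-dominant band calls.

Each call is the set of allele sizes (bp) a line shows at a marker: one size
for a homozygote, two for a heterozygote, ``None`` for missing.  Calls
serialize as slash-joined sizes ("191/218") with "NA" for missing, so the
matrix round-trips losslessly through CSV/TSV.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import pandas as pd

MISSING_TOKEN = "NA"

Call = Optional[frozenset]


def format_call(call: Call) -> str:
    if call is None:
        return MISSING_TOKEN
    return "/".join(str(a) for a in sorted(call))


def parse_call(token: str) -> Call:
    token = str(token).strip()
    if token in ("", MISSING_TOKEN, "nan"):
        return None
    alleles = frozenset(int(round(float(t))) for t in token.split("/"))
    if not 1 <= len(alleles) <= 2:
        raise ValueError(f"call {token!r} has {len(alleles)} distinct alleles")
    return alleles


class GenotypeMatrix:
    """Ordered lines x markers table of co-dominant allele-size calls."""

    def __init__(
        self,
        line_ids: Iterable[str],
        marker_ids: Iterable[str],
        calls: Mapping[tuple[str, str], Call],
    ) -> None:
        self.line_ids = list(line_ids)
        self.marker_ids = list(marker_ids)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        self._calls: dict[tuple[str, str], Call] = {}
        for line in self.line_ids:
            for marker in self.marker_ids:
                call = calls.get((line, marker))
                if call is not None:
                    call = frozenset(call)
                    if not 1 <= len(call) <= 2:
                        raise ValueError(
                            f"call for ({line}, {marker}) has {len(call)} alleles"
                        )
                self._calls[(line, marker)] = call

    def get(self, line: str, marker: str) -> Call:
        return self._calls[(line, marker)]

    def marker_calls(self, marker: str) -> dict[str, Call]:
        """All calls for one marker, keyed by line id (line order preserved)."""
        return {line: self._calls[(line, marker)] for line in self.line_ids}

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            m: [format_call(self._calls[(line, m)]) for line in self.line_ids]
            for m in self.marker_ids
        }
        return pd.DataFrame(data, index=pd.Index(self.line_ids, name="line_id"))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        calls = {
            (str(line), str(marker)): parse_call(df.at[line, marker])
            for line in df.index
            for marker in df.columns
        }
        return cls([str(i) for i in df.index], [str(c) for c in df.columns], calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and self._calls == other._calls
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({len(self.line_ids)} lines x "
            f"{len(self.marker_ids)} markers)"
        )
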