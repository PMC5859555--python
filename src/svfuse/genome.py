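"""Linear ("flattened") genome coordinates.

Chromosomes are concatenated in a fixed order; a flattened position is the
0-based offset into the concatenation.  All interval arithmetic elsewhere in
the package operates on flattened, 0-based, inclusive coordinates.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from svfuse.errors import DataError


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome table with cumulative offsets for flattening."""

    contigs: tuple[tuple[str, int], ...]
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)
    _starts: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise DataError("duplicate chromosome names in genome table")
        offsets: dict[str, int] = {}
        starts: list[int] = []
        total = 0
        for name, length in self.contigs:
            if length <= 0:
                raise DataError(f"non-positive length for contig {name!r}")
            offsets[name] = total
            starts.append(total)
            total += length
        object.__setattr__(self, "_offsets", offsets)
        object.__setattr__(self, "_starts", tuple(starts))

    @classmethod
    def from_pairs(cls, pairs) -> "Genome":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @property
    def size(self) -> int:
        """Total flattened length in bp."""
        return sum(l for _, l in self.contigs)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    def __contains__(self, contig: str) -> bool:
        return contig in self._offsets

    def length_of(self, contig: str) -> int:
        for name, length in self.contigs:
            if name == contig:
                return length
        raise DataError(f"unknown contig {contig!r}")

    def flatten(self, contig: str, pos: int) -> int:
        """Map a 0-based position on ``contig`` to a flattened position."""
        try:
            off = self._offsets[contig]
        except KeyError:
            raise DataError(f"unknown contig {contig!r}") from None
        length = self.length_of(contig)
        if not 0 <= pos < length:
            raise DataError(f"position {pos} outside contig {contig!r} (length {length})")
        return off + pos

    def unflatten(self, fpos: int) -> tuple[str, int]:
        """Inverse of :meth:`flatten`."""
        if not 0 <= fpos < self.size:
            raise DataError(f"flattened position {fpos} outside genome of size {self.size}")
        i = bisect_right(self._starts, fpos) - 1
        name, _ = self.contigs[i]
        return name, fpos - self._starts[i]

    def contig_span(self, fpos: int) -> tuple[int, int]:
        """Flattened [start, end] inclusive of the contig containing ``fpos``."""
        name, _ = self.unflatten(fpos)
        off = self._offsets[name]
        return off, off + self.length_of(name) - 1

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.contigs:
                fh.write(f"{name}\t{length}\n")

    @classmethod
    def from_tsv(cls, path) -> "Genome":
        pairs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise DataError(f"{path}:{lineno}: expected <name>\\t<length>")
                try:
                    pairs.append((fields[0], int(fields[1])))
                except ValueError:
                    raise DataError(f"{path}:{lineno}: length {fields[1]!r} is not an integer")
        return cls.from_pairs(pairs)
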