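"""One-to-one ortholog interval maps between two genome coordinate systems.

The map is a set of reciprocal-best alignment blocks: each block pairs an
interval in the source genome with an equal-length interval in the
destination genome, optionally on the minus strand. Blocks are non-
overlapping on both sides (one-to-one). Projection of a query interval
intersects it with the blocks, maps each piece linearly (strand-aware) and
returns the minimal destination interval spanning the pieces; queries that
touch no block are unmappable.

The native on-disk format is a 7-column TSV
(#src_chrom src_start src_end dst_chrom dst_start dst_end strand); a
minimal UCSC chain ingest that collapses aligned blocks to this TSV is
provided for convenience, but block semantics (no per-block indels) are the
contract.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .intervals import Interval

__all__ = ["OrthologBlock", "OrthologMap", "load_map", "chain_to_blocks"]


@dataclass(frozen=True)
class OrthologBlock:
    src: Interval
    dst: Interval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.src.length != self.dst.length:
            raise ValueError(
                f"block src/dst length mismatch: {self.src} vs {self.dst}"
            )

    def map_position(self, pos: int) -> tuple[str, int]:
        """Map a src position (must lie in the block) into dst coordinates."""
        off = pos - self.src.start
        if self.strand == "+":
            return self.dst.chrom, self.dst.start + off
        return self.dst.chrom, self.dst.end - 1 - off

    def map_interval(self, start: int, end: int) -> Interval:
        """Map a src sub-interval [start, end) fully inside the block."""
        off_s = start - self.src.start
        off_e = end - self.src.start
        if self.strand == "+":
            return Interval(self.dst.chrom, self.dst.start + off_s, self.dst.start + off_e)
        return Interval(self.dst.chrom, self.dst.end - off_e, self.dst.end - off_s)


class OrthologMap:
    """Collection of one-to-one blocks indexed by source chromosome."""

    def __init__(self, blocks: list[OrthologBlock]):
        self._validate(blocks)
        self.blocks = list(blocks)
        self._trees: dict[str, IntervalTree] = {}
        for blk in blocks:
            tree = self._trees.setdefault(blk.src.chrom, IntervalTree())
            tree.addi(blk.src.start, blk.src.end, blk)

    @staticmethod
    def _validate(blocks: list[OrthologBlock]) -> None:
        for side in ("src", "dst"):
            seen: dict[str, list[tuple[int, int, int]]] = {}
            for i, blk in enumerate(blocks):
                iv = getattr(blk, side)
                seen.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
            for chrom, spans in seen.items():
                spans.sort()
                for (s1, e1, i1), (s2, e2, i2) in zip(spans, spans[1:]):
                    if s2 < e1:
                        raise ValueError(
                            f"ortholog map not one-to-one: blocks {i1} and {i2} "
                            f"overlap on {side} {chrom}:{s2}-{min(e1, e2)}"
                        )

    def __len__(self) -> int:
        return len(self.blocks)

    def project(self, query: Interval) -> Interval | None:
        """Project a query into destination coordinates; None if unmappable.

        Each intersected piece is mapped linearly within its block. If the
        pieces land on several destination chromosomes, the chromosome
        carrying the largest projected length wins (ties broken by the
        lexicographically first chromosome); the result is the minimal
        destination interval spanning the winning pieces.
        """
        tree = self._trees.get(query.chrom)
        if tree is None:
            return None
        pieces: list[Interval] = []
        for hit in tree.overlap(query.start, query.end):
            blk: OrthologBlock = hit.data
            s = max(query.start, blk.src.start)
            e = min(query.end, blk.src.end)
            if e > s:
                pieces.append(blk.map_interval(s, e))
        if not pieces:
            return None
        by_chrom: dict[str, list[Interval]] = {}
        for p in pieces:
            by_chrom.setdefault(p.chrom, []).append(p)
        # Largest projected length wins; ties go to the lexicographically
        # first destination chromosome.
        chrom, group = min(
            by_chrom.items(),
            key=lambda kv: (-sum(p.length for p in kv[1]), kv[0]),
        )
        return Interval(chrom, min(p.start for p in group), max(p.end for p in group))


def load_map(path) -> OrthologMap:
    """Load the 7-column block TSV; invariant violations name the lines."""
    blocks: list[OrthologBlock] = []
    lines: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            sc, ss, se, dc, ds, de, strand = parts
            try:
                blk = OrthologBlock(
                    Interval(sc, int(ss), int(se)),
                    Interval(dc, int(ds), int(de)),
                    strand,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            blocks.append(blk)
            lines.append(lineno)
    try:
        return OrthologMap(blocks)
    except ValueError as exc:
        # Re-raise with file context; the message already names block indices.
        idx_to_line = {i: ln for i, ln in enumerate(lines)}
        msg = str(exc)
        for i, ln in idx_to_line.items():
            msg = msg.replace(f"blocks {i} ", f"lines {ln} ").replace(f"and {i} ", f"and {ln} ")
        raise ValueError(f"{path}: {msg}") from exc


def write_map(m: OrthologMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#src_chrom\tsrc_start\tsrc_end\tdst_chrom\tdst_start\tdst_end\tstrand\n")
        for blk in m.blocks:
            fh.write(
                f"{blk.src.chrom}\t{blk.src.start}\t{blk.src.end}\t"
                f"{blk.dst.chrom}\t{blk.dst.start}\t{blk.dst.end}\t{blk.strand}\n"
            )


def reverse_map(m: OrthologMap) -> OrthologMap:
    """Swap src and dst (valid because blocks are one-to-one both ways)."""
    return OrthologMap([OrthologBlock(b.dst, b.src, b.strand) for b in m.blocks])


def chain_to_blocks(path) -> OrthologMap:
    """Collapse a UCSC chain file into ungapped ortholog blocks.

    Each aligned run of a chain becomes one block; chain gaps separate
    blocks. Minus-strand target chains are converted from the chain's
    reversed-target coordinates to forward-strand coordinates.
    """
    blocks: list[OrthologBlock] = []
    with open(path) as fh:
        header = None
        t_pos = q_pos = 0
        for raw in fh:
            line = raw.strip()
            if line.startswith("chain"):
                f = line.split()
                # chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id
                header = {
                    "tName": f[2], "tSize": int(f[3]), "tStart": int(f[5]),
                    "qName": f[7], "qSize": int(f[8]), "qStrand": f[9],
                    "qStart": int(f[10]),
                }
                t_pos, q_pos = header["tStart"], header["qStart"]
                continue
            if not line or header is None:
                continue
            f = line.split()
            size = int(f[0])
            src = Interval(header["tName"], t_pos, t_pos + size)
            if header["qStrand"] == "+":
                dst = Interval(header["qName"], q_pos, q_pos + size)
                strand = "+"
            else:
                q_size = header["qSize"]
                dst = Interval(header["qName"], q_size - (q_pos + size), q_size - q_pos)
                strand = "-"
            blocks.append(OrthologBlock(src, dst, strand))
            if len(f) == 3:
                t_pos += size + int(f[1])
                q_pos += size + int(f[2])
            else:
                header = None
    return OrthologMap(blocks)
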