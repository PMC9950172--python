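"""Transcript models, coordinate mapping and indel normalization.

A :class:`TranscriptModel` carries exon structure (genomic, 0-based half-open,
in transcript 5'->3' order), transcript-relative CDS bounds, and optionally the
spliced transcript sequence and the underlying contig sequence. All coordinate
conversions between genomic, transcript and coding (c.) space live here, as do
the two deletion-normalization conventions: maximal left shift (VCF) and
maximal 3' shift on the transcript strand (the HGVS 3' rule). Within a repeat
context every equivalent representation of a deletion collapses onto one
canonical form under each convention, and both describe the identical mutated
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_deletion_seq(seq: str, start: int, length: int, mode: str = "vcf_left"):
    """Shift a deletion maximally left or right within its repeat context.

    ``seq`` is the reference string, the deletion removes ``seq[start:start+length]``
    (0-based). Returns the shifted ``(start, length)``. The mutated sequence is
    invariant under the shift, and the operation is idempotent.
    """
    if start < 0 or length < 1 or start + length > len(seq):
        raise ValueError("deletion outside sequence bounds")
    end = start + length
    if mode == "vcf_left":
        while start > 0 and seq[start - 1] == seq[end - 1]:
            start -= 1
            end -= 1
    elif mode == "hgvs_right":
        while end < len(seq) and seq[end] == seq[start]:
            start += 1
            end += 1
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return start, length


@dataclass
class TranscriptModel:
    """Exon/CDS structure plus sequence for one transcript.

    exons: genomic intervals (0-based half-open) ordered 5'->3' along the
        transcript (ascending for '+', descending for '-').
    cds_start/cds_end: transcript-relative, 0-based half-open.
    sequence: spliced transcript-sense sequence (derived from ``genome`` when
        absent but required).
    genome: the contig sequence (synthetic scale), used for intronic context.
    """

    transcript_id: str
    strand: str
    exons: tuple
    cds_start: int
    cds_end: int
    sequence: str | None = None
    chrom: str = "chr1"
    genome: str | None = None
    _tx_bounds: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        for s, e in self.exons:
            if e <= s:
                raise ValueError("exon intervals must be non-empty half-open")
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(
            starts, reverse=True
        )
        if not ordered:
            raise ValueError("exons must be ordered 5'->3' on the transcript strand")
        ivs = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")
        if self.cds_end - self.cds_start < 3:
            raise ValueError("CDS length must be >= 3")
        bounds, off = [], 0
        for s, e in self.exons:
            bounds.append((off, off + (e - s)))
            off += e - s
        self._tx_bounds = tuple(bounds)
        if self.sequence is None and self.genome is not None:
            self.sequence = self._splice_from_genome()
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length must equal total exon length")
        if self.cds_end > self.length:
            raise ValueError("CDS extends beyond transcript")

    # -- geometry ----------------------------------------------------------
    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def _splice_from_genome(self) -> str:
        parts = []
        for s, e in self.exons:
            chunk = self.genome[s:e]
            parts.append(chunk if self.strand == "+" else revcomp(chunk))
        return "".join(parts)

    @property
    def cds_sequence(self) -> str:
        if self.sequence is None:
            raise ValueError(f"{self.transcript_id} has no sequence")
        return self.sequence[self.cds_start : self.cds_end]

    def genomic_to_transcript(self, g: int):
        """Transcript offset of genomic position g, or None if intronic."""
        for (s, e), (ts, _) in zip(self.exons, self._tx_bounds):
            if s <= g < e:
                return ts + (g - s if self.strand == "+" else e - 1 - g)
        return None

    def transcript_to_genomic(self, t: int) -> int:
        for (s, e), (ts, te) in zip(self.exons, self._tx_bounds):
            if ts <= t < te:
                return s + (t - ts) if self.strand == "+" else e - 1 - (t - ts)
        raise ValueError(f"transcript position {t} out of range")

    def c_position(self, t: int) -> int:
        """HGVS c. position of transcript offset t (1-based within the CDS)."""
        return t - self.cds_start + 1 if t >= self.cds_start else t - self.cds_start

    # -- intron context ----------------------------------------------------
    def locate_genomic(self, g: int):
        """Locate genomic position g relative to the transcript.

        Returns ('exonic', tx_offset), ('donor', anchor_tx, +k),
        ('acceptor', anchor_tx, -k) for intronic positions (anchor = nearest
        exonic transcript offset; ties go to the donor side), or
        ('outside', None, distance-to-transcript-span).
        """
        t = self.genomic_to_transcript(g)
        if t is not None:
            return ("exonic", t, 0)
        for i in range(len(self.exons) - 1):
            up, down = self.exons[i], self.exons[i + 1]
            if self.strand == "+":
                lo, hi = up[1], down[0]
                if not lo <= g < hi:
                    continue
                k_donor = g - lo + 1
                k_acc = hi - g
            else:
                lo, hi = down[1], up[0]
                if not lo <= g < hi:
                    continue
                k_donor = up[0] - g
                k_acc = g - down[1] + 1
            donor_anchor = self._tx_bounds[i][1] - 1
            acc_anchor = self._tx_bounds[i + 1][0]
            if k_donor <= k_acc:
                return ("donor", donor_anchor, k_donor)
            return ("acceptor", acc_anchor, -k_acc)
        return ("outside", None, 0)

    def c_notation(self, g: int) -> str:
        """HGVS c.-style description of a genomic position."""
        where, anchor, k = self.locate_genomic(g)
        if where == "exonic":
            return str(self.c_position(anchor))
        if where == "donor":
            return f"{self.c_position(anchor)}+{k}"
        if where == "acceptor":
            return f"{self.c_position(anchor)}{k}"  # k is negative
        raise ValueError(f"position {g} outside transcript span")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_gtf(cls, gtf_path: str, fasta_path: str, transcript_id: str):
        """Build a transcript model from GTF exon/CDS features plus a FASTA."""
        import gffutils
        from pyfaidx import Fasta

        db = gffutils.create_db(
            gtf_path, ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        exons, cds_ivs, strand, chrom = [], [], None, None
        for feat in db.all_features():
            attrs = feat.attributes
            tid = attrs.get("transcript_id", [None])[0]
            if tid != transcript_id:
                continue
            if feat.featuretype == "exon":
                exons.append((feat.start - 1, feat.end))
                strand, chrom = feat.strand, feat.seqid
            elif feat.featuretype == "CDS":
                cds_ivs.append((feat.start - 1, feat.end))
        if not exons:
            raise ValueError(f"transcript {transcript_id} not found in {gtf_path}")
        exons.sort(reverse=(strand == "-"))
        fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
        genome = str(fa[chrom][:])
        model = cls(
            transcript_id=transcript_id, strand=strand, exons=tuple(exons),
            cds_start=0, cds_end=3, chrom=chrom, genome=genome,
        )
        # CDS bounds in transcript coordinates from the CDS features
        cds_tx = sorted(
            t
            for s, e in cds_ivs
            for g in (s, e - 1)
            if (t := model.genomic_to_transcript(g)) is not None
        )
        if cds_tx:
            model.cds_start, model.cds_end = cds_tx[0], cds_tx[-1] + 1
        return model


def normalize_genomic_deletion(
    tx: TranscriptModel, start: int, length: int, mode: str = "vcf_left"
):
    """Normalize a genomic deletion on a transcript's contig.

    ``vcf_left`` always shifts toward lower genomic coordinates; ``hgvs_right``
    shifts 3' along the TRANSCRIPT, i.e. toward higher genomic coordinates on
    '+' transcripts and lower on '-'.
    """
    if tx.genome is None:
        raise ValueError("transcript has no contig sequence to normalize against")
    if mode not in ("vcf_left", "hgvs_right"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "vcf_left":
        seq_mode = "vcf_left"
    else:
        seq_mode = "hgvs_right" if tx.strand == "+" else "vcf_left"
    return normalize_deletion_seq(tx.genome, start, length, seq_mode)
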