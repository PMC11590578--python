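"""Class-code assignment versus an independent base-level oracle."""

import numpy as np
import pytest

from lncscape.annotation import TranscriptomeAnnotation
from lncscape.compare import (
    UNCLASSIFIABLE,
    assign_class_code,
    build_junction_index,
    identify_novel,
    classify_all,
    shares_junction_with,
)

from conftest import make_annotation, make_transcript

# ---------------------------------------------------------------------------
# Brute-force oracle: every structural rule evaluated by exhaustive
# base-set enumeration, independent of the interval arithmetic under test.
# ---------------------------------------------------------------------------

_ORACLE_PRECEDENCE = {"=": 0, "i": 1, "y": 2, "o": 3, "x": 4, "s": 5, "p": 6, "u": 7}


def _bases(t):
    return set(b for e in t.exons for b in range(e.start, e.end))


def _runs(bases):
    """Contiguous runs of a base set, ascending."""
    out, run = [], []
    for b in sorted(bases):
        if run and b != run[-1] + 1:
            out.append((run[0], run[-1] + 1))
            run = []
        run.append(b)
    if run:
        out.append((run[0], run[-1] + 1))
    return out


def _intron_runs(t):
    span = set(range(min(_bases(t)), max(_bases(t)) + 1))
    return _runs(span - _bases(t))


def _junction_chain(t):
    runs = _runs(_bases(t))
    return [(runs[i][1], runs[i + 1][0]) for i in range(len(runs) - 1)]


def _span_inside_any_intron(inner, outer):
    b = _bases(inner)
    lo, hi = min(b), max(b) + 1
    return any(s <= lo and hi <= e for s, e in _intron_runs(outer))


def _oracle_pair(q, ref, run_on):
    if q.chrom != ref.chrom:
        return None
    qb, rb = _bases(q), _bases(ref)
    qlo, qhi = min(qb), max(qb) + 1
    rlo, rhi = min(rb), max(rb) + 1
    span_overlap = qlo < rhi and rlo < qhi
    gap = max(rlo - qhi, qlo - rhi, 0)
    overlap = len(qb & rb)
    if q.strand == ref.strand:
        qj, rj = _junction_chain(q), _junction_chain(ref)
        if qj and qj == rj:
            return "=", overlap
        if not qj and not rj and overlap >= 1:
            return "=", overlap
        if _span_inside_any_intron(q, ref):
            return "i", 0
        if _span_inside_any_intron(ref, q):
            return "y", 0
        if overlap >= 1:
            return "o", overlap
        if not span_overlap and gap <= run_on:
            return "p", -gap
    else:
        if overlap >= 1:
            return "x", overlap
        if _span_inside_any_intron(q, ref):
            return "s", 0
    return None


def oracle_code(query, refs, run_on=2000):
    if query.strand not in "+-":
        return UNCLASSIFIABLE
    best = None
    for ref in refs:
        if ref.strand not in "+-":
            continue
        res = _oracle_pair(query, ref, run_on)
        if res is None:
            continue
        code, score = res
        key = (_ORACLE_PRECEDENCE[code], -score)
        if best is None or key < best[0]:
            best = (key, code)
    return best[1] if best else "u"


# ---------------------------------------------------------------------------
# Randomized fixture generation covering all eight codes
# ---------------------------------------------------------------------------

def _rand_ref(rng, origin=0, strand=None):
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_exons = int(rng.integers(1, 4))
    pos = origin + int(rng.integers(0, 200))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(80, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(260, 600))
    return make_transcript(f"R{rng.integers(1e9)}", exons, strand=strand)


def _rand_query(rng, ref):
    """Draw a query by a random strategy relative to the reference."""
    strand = ref.strand if rng.random() < 0.5 else ("-" if ref.strand == "+" else "+")
    strategy = rng.choice(
        ["identical", "in_intron", "contain_ref", "exon_overlap", "nearby", "far", "random"]
    )
    span = ref.span
    if strategy == "identical":
        return make_transcript("Q", [(e.start, e.end) for e in ref.exons], strand=ref.strand)
    if strategy == "in_intron" and ref.junctions:
        s, e = ref.junctions[int(rng.integers(len(ref.junctions)))]
        if e - s > 40:
            a = s + int(rng.integers(1, 20))
            b = e - int(rng.integers(1, 20))
            if a < b:
                return make_transcript("Q", [(a, b)], strand=strand)
    if strategy == "contain_ref":
        return make_transcript(
            "Q",
            [(max(0, span.start - 300), max(1, span.start - 50)),
             (span.end + 50, span.end + 300)],
            strand=strand,
        )
    if strategy == "exon_overlap":
        e = ref.exons[int(rng.integers(len(ref.exons)))]
        shift = int(rng.integers(-60, 60))
        a = max(0, e.start + shift)
        return make_transcript("Q", [(a, a + int(rng.integers(60, 400)))], strand=strand)
    if strategy == "nearby":
        d = int(rng.integers(1, 2600))
        a = span.end + d
        return make_transcript("Q", [(a, a + int(rng.integers(100, 400)))], strand=strand)
    if strategy == "far":
        a = span.end + int(rng.integers(3000, 8000))
        return make_transcript("Q", [(a, a + 200)], strand=strand)
    # fully random geometry
    pos = int(rng.integers(max(0, span.start - 1500), span.end + 1500))
    exons = []
    for _ in range(int(rng.integers(1, 4))):
        length = int(rng.integers(50, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 500))
    return make_transcript("Q", exons, strand=strand)


def random_pairs(seed, n):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        refs = [_rand_ref(rng)]
        if rng.random() < 0.3:
            refs.append(_rand_ref(rng, origin=int(rng.integers(0, 2000))))
        yield _rand_query(rng, refs[0]), refs


def test_oracle_equivalence_randomized():
    """The assigner matches the exhaustive base-level checker on several
    hundred randomized (query, reference) pairs spanning all codes."""
    seen = set()
    for query, refs in random_pairs(seed=202, n=400):
        ann = make_annotation(refs)
        got = assign_class_code(query, ann).code
        want = oracle_code(query, refs)
        assert got == want, f"{query} vs {[r.transcript_id for r in refs]}"
        seen.add(got)
    assert {"=", "i", "o", "x", "u", "p"} <= seen


class TestSpecificGeometries:
    def setup_method(self):
        # two-exon reference: exons (100,110) and (300,400), intron (110,300)
        self.ref = make_transcript("R.1", [(100, 110), (300, 400)], strand="+")
        self.ann = make_annotation([self.ref])

    def test_identical_multi_exon_is_equal(self):
        q = make_transcript("Q", [(90, 110), (300, 420)], strand="+")
        assert assign_class_code(q, self.ann).code == "="

    def test_intronic_same_strand(self):
        q = make_transcript("Q", [(150, 180)], strand="+")
        a = assign_class_code(q, self.ann)
        assert a.code == "i"
        assert a.best_reference_id == "R.1"

    def test_intron_contained_opposite_strand(self):
        q = make_transcript("Q", [(150, 180)], strand="-")
        assert assign_class_code(q, self.ann).code == "s"

    def test_exonic_overlap_opposite_strand(self):
        q = make_transcript("Q", [(305, 350)], strand="-")
        assert assign_class_code(q, self.ann).code == "x"

    def test_reference_contained_in_query_intron(self):
        q = make_transcript("Q", [(10, 60), (500, 600)], strand="+")
        assert assign_class_code(q, self.ann).code == "y"

    def test_run_on_inside_and_outside_distance(self):
        near = make_transcript("Q", [(900, 1100)], strand="+")  # 500 nt away
        far = make_transcript("Q", [(2900, 3100)], strand="+")  # 2500 nt away
        assert assign_class_code(near, self.ann, run_on_distance=2000).code == "p"
        assert assign_class_code(far, self.ann, run_on_distance=2000).code == "u"

    def test_unknown_strand_is_unclassifiable_not_raised(self):
        q = make_transcript("Q", [(305, 350)], strand=".")
        assert assign_class_code(q, self.ann).code == UNCLASSIFIABLE


def test_precedence_independent_of_reference_order():
    """Permuting reference transcript order never changes the code."""
    refs = [
        make_transcript("RA", [(100, 110), (300, 400)], strand="+"),
        make_transcript("RB", [(120, 290)], strand="+"),
        make_transcript("RC", [(50, 450)], strand="-"),
    ]
    q = make_transcript("Q", [(150, 180)], strand="+")
    codes = set()
    for order in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
        ann = make_annotation([refs[i] for i in order])
        codes.add(assign_class_code(q, ann).code)
    assert len(codes) == 1


def test_strand_antisymmetry_on_overlap_fixtures():
    """Flipping the query strand maps o→x on pure exonic overlap and
    i→s on intron containment."""
    ref = make_transcript("R", [(100, 200), (500, 700)], strand="+")
    ann = make_annotation([ref])
    over_plus = make_transcript("Q", [(150, 250)], strand="+")
    over_minus = make_transcript("Q", [(150, 250)], strand="-")
    assert assign_class_code(over_plus, ann).code == "o"
    assert assign_class_code(over_minus, ann).code == "x"
    in_plus = make_transcript("Q", [(250, 460)], strand="+")
    in_minus = make_transcript("Q", [(250, 460)], strand="-")
    assert assign_class_code(in_plus, ann).code == "i"
    assert assign_class_code(in_minus, ann).code == "s"


class TestJunctionIndex:
    def test_single_transcript(self):
        t = make_transcript("T", [(100, 200), (300, 400)])
        assert len(build_junction_index([t])) == 1

    def test_shared_junction_counted_once(self):
        a = make_transcript("A", [(100, 200), (300, 400)])
        b = make_transcript("B", [(50, 200), (300, 500)])
        assert len(build_junction_index([a, b])) == 1

    def test_biotype_filter_and_brute_force_union(self, default_bundle):
        coding = [t for t in default_bundle.reference if t.biotype == "protein_coding"]
        idx = build_junction_index(default_bundle.reference, "protein_coding")
        expected = set()
        for t in coding:
            for j in t.junctions:
                expected.add((t.chrom, j[0], j[1], t.strand))
        assert idx.junctions == expected

    def test_single_exon_query_never_shares(self):
        idx = build_junction_index([make_transcript("T", [(100, 200), (300, 400)])])
        assert not shares_junction_with(make_transcript("Q", [(100, 400)]), idx)

    def test_exact_match_semantics(self):
        idx = build_junction_index([make_transcript("T", [(100, 200), (300, 400)])])
        hit = make_transcript("Q", [(150, 200), (300, 350)])
        shifted = make_transcript("Q", [(150, 201), (300, 350)])
        assert shares_junction_with(hit, idx)
        assert not shares_junction_with(shifted, idx)


class TestIdentifyNovel:
    def test_assembly_equal_to_reference_yields_nothing(self):
        ref = make_annotation(
            [make_transcript("R1", [(100, 200), (300, 400)]),
             make_transcript("R2", [(1000, 1500)])],
        )
        asm = make_annotation(
            [make_transcript("A1", [(100, 200), (300, 400)]),
             make_transcript("A2", [(1000, 1500)])],
            source="assembly",
        )
        assert identify_novel(asm, ref) == []

    def test_partition_every_query_appears_once(self, default_bundle):
        assignments = classify_all(default_bundle.assembly, default_bundle.reference)
        assert len(assignments) == len(default_bundle.assembly)
        novel = identify_novel(default_bundle.assembly, default_bundle.reference)
        n_equal = sum(a.code == "=" for a in assignments)
        assert len(novel) + n_equal == len(default_bundle.assembly)

    def test_planted_novels_recovered(self, default_bundle):
        """Every planted novel transcript (and no annotated copy) comes
        back from identify_novel with its planted code."""
        truth = default_bundle.truth.records
        novel = {a.query_id: a.code for a in identify_novel(
            default_bundle.assembly, default_bundle.reference
        )}
        for rec in truth.values():
            if rec.role in ("novel_lncrna", "novel_coding_isoform", "novel_short"):
                assert novel[rec.transcript_id] == rec.class_code
            elif rec.role == "annotated_copy":
                assert rec.transcript_id not in novel
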