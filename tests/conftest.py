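import numpy as np
import pytest

from cnvbench.core import CNClass, CallSet, GenomicSegment


def seg(chrom=1, start=0, end=100, cls=CNClass.LOSS, **kw):
    """Terse GenomicSegment factory for tests."""
    return GenomicSegment(chrom=chrom, start=start, end=end, cn_class=CNClass(cls), **kw)


@pytest.fixture
def make_callset():
    def _make(segments, sample_id="S1", tool_id="T1"):
        return CallSet(sample_id, tool_id, segments)

    return _make


def brute_force_coverage(target, others, same_class=True):
    """Per-base oracle for coverage_fraction on integer coordinates."""
    covered = np.zeros(target.end - target.start, dtype=bool)
    for o in others:
        if o.chrom != target.chrom:
            continue
        if same_class and o.cn_class is not target.cn_class:
            continue
        lo = max(o.start, target.start) - target.start
        hi = min(o.end, target.end) - target.start
        if hi > lo:
            covered[lo:hi] = True
    return covered.mean()


def brute_force_depth(intervals, lo, hi):
    """Per-base stacking-depth oracle over [lo, hi)."""
    depth = np.zeros(hi - lo, dtype=int)
    for s, e in intervals:
        s, e = max(s, lo), min(e, hi)
        if e > s:
            depth[s - lo : e - lo] += 1
    return depth
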