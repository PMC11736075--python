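import itertools

import pytest

from ssrcurate import SampleRecord, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_sample(sid, calls, panel, **meta):
    """Build a SampleRecord whose profile covers the whole panel.

    ``calls`` maps marker -> iterable of AFLs for the markers of interest;
    every other marker gets a default two-allele call so distances stay
    well-defined.
    """
    profile = {m: frozenset({100, 120}) for m in panel.names}
    for marker, alleles in calls.items():
        profile[marker] = frozenset(alleles)
    return SampleRecord(sample_id=sid, profile=profile, **meta)


def brute_force_common(a, b, tolerance_bp):
    """Exhaustive maximum one-to-one matching between two AFL sets where
    x may pair with y iff |x - y| <= tolerance.  Independent oracle for the
    greedy matcher; exponential, only for tiny sets."""
    a = sorted(a)
    b = sorted(b)
    best = 0
    for k in range(min(len(a), len(b)), 0, -1):
        for sub_a in itertools.combinations(a, k):
            for sub_b in itertools.permutations(b, k):
                if all(abs(x - y) <= tolerance_bp for x, y in zip(sub_a, sub_b)):
                    return k
    return best
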