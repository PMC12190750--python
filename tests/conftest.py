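import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_records(rng, n, mod_codes=("a", "m", "17596", "17802")):
    """Random but valid bedMethyl records for round-trip tests."""
    from dmscall.io_formats import SiteKey, SiteRecord

    records = []
    seen = set()
    while len(records) < n:
        ref = f"tx{rng.integers(0, 200):04d}"
        start = int(rng.integers(0, 100000))
        strand = "+" if rng.random() < 0.9 else "-"
        mod = mod_codes[rng.integers(0, len(mod_codes))]
        key = (ref, start, strand, mod)
        if key in seen:
            continue
        seen.add(key)
        n_mod = int(rng.integers(0, 100))
        n_can = int(rng.integers(0, 100))
        n_other = int(rng.integers(0, 5))
        records.append(
            SiteRecord(
                key=SiteKey(ref, start, start + 1, strand, mod),
                sample_id="s1",
                n_valid=n_mod + n_can + n_other,
                n_mod=n_mod,
                n_canonical=n_can,
                n_other=n_other,
            )
        )
    return records
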