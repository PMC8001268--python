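import pytest

from varledger import VariantKey, VariantStore
from varledger.fixtures import ddm_dialect, tss_dialect


def brute_force_changes(store, q):
    """Independent change-search oracle: scan every variant's full history
    through the public history API and apply the query definition literally."""

    def norm(v):
        v = v.strip()
        return v.lower() if q.case_insensitive else v

    prev_set = None if q.previous_in is None else {norm(v) for v in q.previous_in}
    cur_set = None if q.current_equals is None else {norm(v) for v in q.current_equals}
    hits = []
    for _, key in store.iter_variants():
        history = store.attribute_history(key, q.attribute)
        if not history:
            continue
        current = history[-1]
        if cur_set is not None and norm(current.value) not in cur_set:
            continue
        if q.since is not None and current.imported_at < q.since:
            continue
        if prev_set is not None:
            priors = history[-2:-1] if q.strict_previous else history[:-1]
            if not any(norm(e.value) in prev_set for e in priors):
                continue
        hits.append(str(key))
    return hits


@pytest.fixture
def store():
    with VariantStore() as s:
        yield s


@pytest.fixture
def tss_spec():
    return tss_dialect()


@pytest.fixture
def ddm_spec():
    return ddm_dialect()


@pytest.fixture
def brca2_key():
    return VariantKey("chr13", 32936829, "A", "G")
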