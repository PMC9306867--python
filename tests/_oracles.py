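"""Independent brute-force oracles used by the tests.

These deliberately re-derive expected behaviour from first principles
(exhaustive enumeration over the transmission/sampling tree) without
touching the package's simulation path.
"""

from collections import defaultdict


def _cohort_freqs(individuals, observed, hap_names):
    idx = {h: i for i, h in enumerate(hap_names)}
    birth = {r["id"]: r["birth"] for r in individuals}
    counts = defaultdict(lambda: [0.0] * len(hap_names))
    for iid, pair in observed.items():
        for h in pair:
            counts[birth[iid]][idx[h]] += 1
    freq = {y: [c / sum(v) for c in v] for y, v in counts.items()}
    data_years = sorted(freq)

    def lookup(year):
        if year in freq:
            return freq[year]
        nearest = min(data_years, key=lambda d: (abs(d - year), d))
        return freq[nearest]

    return lookup


def _ancestors(individuals, focal):
    by_id = {r["id"]: r for r in individuals}
    seen = set()
    stack = [focal]
    while stack:
        iid = stack.pop()
        if iid in seen:
            continue
        seen.add(iid)
        rec = by_id[iid]
        for parent in (rec["sire"], rec["dam"]):
            if parent is not None:
                stack.append(parent)
    return seen


def exact_drop_distribution(individuals, observed, founder_hi, hap_names, focal):
    """Exact marginal distribution of ``focal``'s unordered diplotype.

    ``individuals``: list of dicts with keys id, sire, dam, birth (parents
    None when unknown).  ``observed``: id -> (hap, hap).  Individuals born
    in or before ``founder_hi`` with observed diplotypes keep them; all
    other alleles branch over Mendelian picks (probability 1/2 each) or
    the observed birth-cohort frequencies when the parent is unknown.
    Enumeration is restricted to the focal individual's ancestor closure,
    which fully determines its marginal.
    """
    cohort_freq = _cohort_freqs(individuals, observed, hap_names)
    relevant = _ancestors(individuals, focal)
    order = sorted(
        (r for r in individuals if r["id"] in relevant),
        key=lambda r: (r["birth"], r["id"]),
    )
    dist: dict[tuple, float] = defaultdict(float)

    def recurse(i, state, prob):
        if i == len(order):
            dist[tuple(sorted(state[focal]))] += prob
            return
        rec = order[i]
        iid = rec["id"]
        if rec["birth"] <= founder_hi and iid in observed:
            state[iid] = observed[iid]
            recurse(i + 1, state, prob)
            del state[iid]
            return
        slot_options = []
        for parent in (rec["sire"], rec["dam"]):
            if parent is not None:
                pair = state[parent]
                slot_options.append([(pair[0], 0.5), (pair[1], 0.5)])
            else:
                freqs = cohort_freq(rec["birth"])
                slot_options.append(
                    [(hap_names[j], f) for j, f in enumerate(freqs) if f > 0]
                )
        for allele0, p0 in slot_options[0]:
            for allele1, p1 in slot_options[1]:
                state[iid] = (allele0, allele1)
                recurse(i + 1, state, prob * p0 * p1)
        del state[iid]

    recurse(0, {}, 1.0)
    return dict(dist)
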