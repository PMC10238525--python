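"""Independent brute-force oracles used by the test suite.

Each oracle deliberately re-derives its quantity in the most literal way
possible (full pairwise rescans, explicit enumeration) so it shares no
code with the implementation it checks.
"""

import numpy as np
import pandas as pd


def brute_force_clump(sumstats, dosages, panel_index, r2_max, window_kb, p_threshold):
    """Literal greedy clumping: re-scan every remaining pair at each step.

    ``panel_index`` maps sumstat rows to dosage columns.  Returns the
    selected row positions (into ``sumstats``) in selection order.
    """
    cand = [
        (sumstats["pval"].iat[i], str(sumstats["chrom"].iat[i]), int(sumstats["pos"].iat[i]), i)
        for i in range(len(sumstats))
        if sumstats["pval"].iat[i] <= p_threshold
    ]
    cand.sort()
    remaining = [c[3] for c in cand]
    selected = []
    while remaining:
        best = remaining.pop(0)
        selected.append(best)
        keep = []
        for other in remaining:
            same_chrom = str(sumstats["chrom"].iat[other]) == str(sumstats["chrom"].iat[best])
            dist = abs(int(sumstats["pos"].iat[other]) - int(sumstats["pos"].iat[best]))
            if same_chrom and dist <= window_kb * 1000:
                x = dosages[:, panel_index[best]]
                z = dosages[:, panel_index[other]]
                if x.std() == 0 or z.std() == 0:
                    r2 = 0.0
                else:
                    r2 = np.corrcoef(x, z)[0, 1] ** 2
                if r2 > r2_max:
                    continue
            keep.append(other)
        remaining = keep
    return selected


def brute_force_unrelated(edges, threshold, ids):
    """Greedy max-degree elimination, re-counting degrees from scratch each step."""
    above = [
        (str(a), str(b))
        for a, b, k in zip(edges["id1"], edges["id2"], edges["kinship"])
        if k > threshold and str(a) != str(b)
    ]
    alive = set(map(str, ids)) | {x for e in above for x in e}
    while True:
        deg = {}
        for a, b in above:
            if a in alive and b in alive:
                deg[a] = deg.get(a, 0) + 1
                deg[b] = deg.get(b, 0) + 1
        if not deg:
            return alive
        top = max(deg.values())
        victim = max(n for n, d in deg.items() if d == top)
        alive.discard(victim)


def pair_counting_auc(y, score):
    """All-pairs enumeration AUC with half-credit for tied scores."""
    y = np.asarray(y).astype(bool)
    s = np.asarray(score, float)
    wins = ties = total = 0
    for i in np.flatnonzero(y):
        for j in np.flatnonzero(~y):
            total += 1
            if s[i] > s[j]:
                wins += 1
            elif s[i] == s[j]:
                ties += 1
    return (wins + 0.5 * ties) / total


def random_clump_instance(seed, max_variants=60, n_panel=200):
    """A random clumping instance: correlated panel dosages + arbitrary p-values."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, max_variants + 1))
    block = int(rng.integers(1, 8))
    rho = float(rng.uniform(0.1, 0.95))
    # correlated standard normals -> thresholded to dosages
    shared = rng.standard_normal((n_panel, (m + block - 1) // block))
    z = (
        np.sqrt(rho) * shared[:, np.arange(m) // block]
        + np.sqrt(1 - rho) * rng.standard_normal((n_panel, m))
    )
    p_freq = rng.uniform(0.1, 0.9, m)
    from scipy import stats as sps

    dos = (sps.norm.cdf(z) < p_freq).astype(float) + (
        sps.norm.cdf(rng.standard_normal((n_panel, m))) < p_freq
    ).astype(float)
    chrom = rng.choice(["1", "2"], m)
    pos = rng.choice(np.arange(1, 5 * m + 1) * int(rng.integers(5_000, 400_000)), m, replace=False)
    ss = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "beta": rng.normal(size=m),
            "se": 0.1,
            "pval": 10.0 ** rng.uniform(-12, 0, m),
            "eaf": p_freq,
            "n": n_panel,
        }
    )
    # dosage column j corresponds to sumstat row j
    return ss, dos, rng
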