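"""Brute-force reference implementations used to cross-check the selectors."""

import numpy as np


def brute_force_select(trajs, param_counts, bin_width=50, n_bins=10):
    """Direct re-implementation with explicit loops, for cross-checking."""
    n_epochs = min(t.shape[1] for t in trajs)
    n_bins_eff = min(n_bins, -(-n_epochs // bin_width))
    bin_scores = []
    for t in trajs:
        scores = []
        for b in range(n_bins_eff):
            acc = []
            for e in range(b * bin_width, min((b + 1) * bin_width, n_epochs)):
                col = t[:, e]
                acc.append(col.mean() + col.std(ddof=0))
            scores.append(sum(acc) / len(acc))
        bin_scores.append(scores)
    wins = [0] * len(trajs)
    for b in range(n_bins_eff):
        vals = [bs[b] for bs in bin_scores]
        lo = min(vals)
        for i, v in enumerate(vals):
            if v == lo:
                wins[i] += 1
    m = max(wins)
    cands = [i for i, w in enumerate(wins) if w == m]
    if len(cands) > 1:
        pc = [param_counts[i] for i in cands]
        cands = [i for i in cands if param_counts[i] == min(pc)]
    if len(cands) > 1:
        means = [trajs[i][:, :n_epochs].mean() for i in cands]
        cands = [cands[int(np.argmin(means))]]
    return cands[0]


def brute_force_epochs(traj, window=20):
    """Scan every full window; strictly-smaller keeps the earliest minimum."""
    summed = traj.sum(axis=0)
    best_val, best_e = np.inf, None
    for end in range(window, summed.size + 1):
        v = summed[end - window : end].mean()
        if v < best_val:
            best_val, best_e = v, end
    return best_e
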