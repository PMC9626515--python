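"""Brute-force reference implementations used by multiple test modules."""

import numpy as np


def persev_oracle(rows):
    """Independent list-based perseveration scan."""
    total_err, total_qual = 0, 0
    for _, blk in rows.groupby("block"):
        recs = list(blk[["choice", "outcome", "correct", "stage"]].itertuples(index=False))
        corr_stim = [r.choice if r.correct else 1 - r.choice for r in recs]
        stages = sorted({r.stage for r in recs})
        for s in stages[1:]:
            idx = [i for i, r in enumerate(recs) if r.stage == s]
            if not idx:
                continue
            prev_idx = [i for i, r in enumerate(recs) if r.stage == s - 1]
            old = corr_stim[prev_idx[-1]]
            rev = None
            for i in idx:
                if recs[i].choice == old and recs[i].outcome == -1:
                    rev = i
                    break
            if rev is None:
                continue
            run = 0
            j = rev + 1
            while j < len(recs) and recs[j].choice == old:
                run += 1
                j += 1
            total_err += run
            total_qual += run >= 1
    rate = total_err / total_qual if total_qual else float("nan")
    return total_err, total_qual, rate


def wsls_oracle(rows):
    """Direct enumeration of win-stay / lose-shift over trial pairs."""
    ws_pairs, ls_pairs = [], []
    for _, blk in rows.groupby("block"):
        ch = blk["choice"].tolist()
        oc = blk["outcome"].tolist()
        for t in range(1, len(ch)):
            if oc[t - 1] == 1:
                ws_pairs.append(ch[t] == ch[t - 1])
            else:
                ls_pairs.append(ch[t] != ch[t - 1])
    return float(np.mean(ws_pairs)), float(np.mean(ls_pairs))


def negfb_code_oracle(choices, outcomes, t):
    """Rule-table cumulative-negative-feedback code for trial t (>= 1)."""
    if outcomes[t - 1] == 1:
        return 0
    code = 1
    if t >= 2 and outcomes[t - 2] == -1 and choices[t - 1] == choices[t - 2]:
        code = 2
        if t >= 3 and outcomes[t - 3] == -1 and choices[t - 2] == choices[t - 3]:
            code = 3
    return code
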