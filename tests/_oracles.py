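"""Independent brute-force oracles used to validate the metric implementations.

Everything here is written as plain double loops / direct formula
transcriptions, deliberately sharing no code with the package.
"""

import math

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge


def ci_bruteforce(y_true, y_pred):
    """O(n^2) pair enumeration of the concordance index."""
    num = 0.0
    den = 0
    n = len(y_true)
    for i in range(n):
        for j in range(n):
            if y_true[i] > y_true[j]:
                den += 1
                if y_pred[i] > y_pred[j]:
                    num += 1.0
                elif y_pred[i] == y_pred[j]:
                    num += 0.5
    return num / den


def aupr_bruteforce(labels, scores):
    """Average precision by walking the ranked list one threshold at a time."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    tp = 0
    total_pos = sum(labels)
    ap = 0.0
    for rank, i in enumerate(order, start=1):
        if labels[i] == 1:
            tp += 1
            ap += tp / rank
    return ap / total_pos


def rm2_formula(y, yhat):
    """Direct transcription of r_m^2 = r^2 (1 - sqrt(|r^2 - r0^2|)) using
    plain Python arithmetic."""
    n = len(y)
    my = sum(y) / n
    mp = sum(yhat) / n
    sxy = sum((a - my) * (b - mp) for a, b in zip(y, yhat))
    sxx = sum((a - my) ** 2 for a in y)
    syy = sum((b - mp) ** 2 for b in yhat)
    r2 = (sxy * sxy) / (sxx * syy)
    k = sum(a * b for a, b in zip(y, yhat)) / sum(a * a for a in y)
    ss_res = sum((b - k * a) ** 2 for a, b in zip(y, yhat))
    r02 = 1.0 - ss_res / syy
    return r2 * (1.0 - math.sqrt(abs(r2 - r02)))


def mcnemar_exact_binomial(b, c):
    """Exact two-sided binomial McNemar p-value via factorials."""
    n = b + c
    k = min(b, c)
    p = sum(math.comb(n, i) for i in range(k + 1)) * 0.5**n
    return min(1.0, 2.0 * p)


def bilinear_ridge_ci(drug_mat, prot_mat, di, pj, y, train_idx, test_idx,
                      n_components=8, alpha=1.0):
    """Bilinear ridge oracle: PCA-reduce each side, regress y on the outer
    product of the reduced vectors. The canonical linearisation of a
    bilinear form; used to certify that synthetic signal is learnable."""
    dr = PCA(n_components=n_components, random_state=0).fit_transform(drug_mat)
    pr = PCA(n_components=n_components, random_state=0).fit_transform(prot_mat)
    cross = np.einsum("nk,nl->nkl", dr[di], pr[pj]).reshape(len(di), -1)
    # linear main effects complete the affine-shifted bilinear form
    feats = np.concatenate([cross, dr[di], pr[pj]], axis=1)
    model = Ridge(alpha=alpha)
    model.fit(feats[train_idx], y[train_idx])
    return model.predict(feats[test_idx])
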