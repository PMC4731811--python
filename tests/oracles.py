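"""Independent brute-force oracles used by the unit and acceptance tests.

Each helper re-derives a quantity with a deliberately naive algorithm
(neighbour loops, BFS, explicit refits) that shares no code with the
package implementation it checks.
"""

from collections import deque

import numpy as np
import scipy.linalg

from callus.geometry import CALLUS_CODES


def floodfill_union(bone_binary, domain):
    """Non-union flag by plain BFS over bone-positive callus cells."""
    callus = np.isin(domain.region, CALLUS_CODES)
    bone = np.asarray(bone_binary, bool) & callus
    iz0 = int(np.searchsorted(domain.z_centers, domain.cortical_end_z))
    iz0 = min(iz0, domain.n_z - 1)
    seen = np.zeros_like(bone)
    q = deque((iz0, ir) for ir in range(domain.n_r) if bone[iz0, ir])
    for cell in q:
        seen[cell] = True
    while q:
        iz, ir = q.popleft()
        for dz, dr in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            jz, jr = iz + dz, ir + dr
            if (0 <= jz < domain.n_z and 0 <= jr < domain.n_r
                    and bone[jz, jr] and not seen[jz, jr]):
                seen[jz, jr] = True
                q.append((jz, jr))
    return 0 if seen[-1, :].any() else 1


def _connected(n_nodes, edges, a, b):
    adj = {i: [] for i in range(n_nodes)}
    for (u, v) in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen = {a}
    q = deque([a])
    while q:
        u = q.popleft()
        if u == b:
            return True
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                q.append(w)
    return b in seen


def brute_perfusion(n_nodes, edges, entry_nodes):
    """Per-edge perfusion by exhaustive bridge enumeration.

    Augment with a super-node (index n_nodes) joined to every entry node.
    An edge is perfused iff it is connected to the super-node and is not a
    bridge (its endpoints stay connected after its removal).
    """
    sup = n_nodes
    aug = list(edges) + [(sup, e) for e in entry_nodes]
    flags = {}
    for e in edges:
        rest = [x for x in aug if x != e and x != (e[1], e[0])]
        on_cycle = _connected(n_nodes + 1, rest, e[0], e[1])
        supplied = _connected(n_nodes + 1, aug, e[0], sup)
        flags[(min(e), max(e))] = bool(on_cycle and supplied)
    return flags


def dense_diffusion_step(field, domain, D, dt):
    """Diffusion over dt by dense matrix exponential of a neighbour-loop
    Laplacian (zero-flux at callus borders)."""
    callus = np.isin(domain.region, CALLUS_CODES)
    cells = [(iz, ir) for iz in range(domain.n_z) for ir in range(domain.n_r)
             if callus[iz, ir]]
    index = {c: k for k, c in enumerate(cells)}
    n = len(cells)
    L = np.zeros((n, n))
    for (iz, ir) in cells:
        i = index[(iz, ir)]
        for dz, dr, h in ((1, 0, domain.h_z), (-1, 0, domain.h_z),
                          (0, 1, domain.h_r), (0, -1, domain.h_r)):
            j = index.get((iz + dz, ir + dr))
            if j is not None:
                L[i, j] += 1.0 / h ** 2
                L[i, i] -= 1.0 / h ** 2
    u = np.array([field[c] for c in cells])
    u = scipy.linalg.expm(D * dt * L) @ u
    out = np.array(field, dtype=float)
    for c, val in zip(cells, u):
        out[c] = val
    return out


def refit_loo(gp, i):
    """Prediction at training point i from an explicit refit without it,
    holding the fitted kernel hyperparameters fixed."""
    from sklearn.gaussian_process import GaussianProcessRegressor

    X = gp.X_train_
    ys = (gp.y_train_ - gp.y_mean_) / gp.y_std_
    keep = np.arange(len(ys)) != i
    refit = GaussianProcessRegressor(kernel=gp.gp_.kernel_, optimizer=None)
    refit.fit(X[keep], ys[keep])
    mu = refit.predict(X[i:i + 1])[0]
    return gp.y_mean_ + gp.y_std_ * mu


def double_loop_sobol(f, ranges, n_outer=256, n_inner=256, seed=0):
    """First-order Sobol indices by the naive double-loop estimator."""
    ranges = np.asarray(ranges, float)
    d = len(ranges)
    rng = np.random.default_rng(seed)

    def draw(n):
        return ranges[:, 0] + rng.random((n, d)) * (ranges[:, 1] - ranges[:, 0])

    base = draw(4096)
    V = np.var(f(base))
    out = np.empty(d)
    for i in range(d):
        means = np.empty(n_outer)
        xi = draw(n_outer)[:, i]
        for k in range(n_outer):
            X = draw(n_inner)
            X[:, i] = xi[k]
            means[k] = f(X).mean()
        out[i] = np.var(means) / V
    return out
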