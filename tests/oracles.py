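"""Independent brute-force oracles for the network dynamics.

These deliberately use per-neuron, per-step, per-synapse Python loops and
share no code with the package implementation, so that agreement is
evidence of correctness rather than of shared bugs.
"""

import numpy as np

SILENT = -1


def naive_forward(raster, bank, cfg):
    """Per-neuron clock simulation of the conv + pooling layers.

    Returns (fired_at, fire_potential, pooling) with the same conventions
    as the package: spikes at input step t are integrated at update step
    t + 1; a threshold crossing fires the highest-potential map at that
    position (ties: lowest map index) and freezes the whole position.
    """
    P = (cfg.n_frames - cfg.win_len) // cfg.stride + 1
    sec_len = P // cfg.n_sections
    fired_at = [[SILENT] * P for _ in range(cfg.n_maps)]
    fire_pot = [[0.0] * P for _ in range(cfg.n_maps)]
    v = [[cfg.v_rest] * P for _ in range(cfg.n_maps)]
    alive = [[True] * P for _ in range(cfg.n_maps)]

    last = int(np.max(raster))
    for s in range(last + 1):
        # deliver every input spike with time s to every live neuron
        for p in range(P):
            start = p * cfg.stride
            for m in range(cfg.n_maps):
                if not alive[m][p]:
                    continue
                inc = 0.0
                for i in range(cfg.win_len):
                    for j in range(cfg.n_bands):
                        if raster[start + i, j] == s:
                            inc += bank[m, p // sec_len, i, j]
                v[m][p] += inc
        # threshold check, position by position
        for p in range(P):
            crossing = [
                m for m in range(cfg.n_maps) if alive[m][p] and v[m][p] >= cfg.v_thresh
            ]
            if not crossing:
                continue
            best = max(crossing, key=lambda m: (v[m][p], -m))
            fired_at[best][p] = s + 1
            fire_pot[best][p] = v[best][p]
            v[best][p] = cfg.v_rest
            for m in range(cfg.n_maps):
                alive[m][p] = False

    pooling = np.zeros((cfg.n_maps, cfg.n_sections), dtype=int)
    for m in range(cfg.n_maps):
        for p in range(P):
            if fired_at[m][p] != SILENT:
                pooling[m, p // sec_len] += 1
    return np.array(fired_at), np.array(fire_pot), pooling


def naive_stdp(bank, raster, winners, a_plus, a_minus, cfg):
    """Synapse-by-synapse application of the soft-bounded STDP rule."""
    P = (cfg.n_frames - cfg.win_len) // cfg.stride + 1
    sec_len = P // cfg.n_sections
    out = bank.copy()
    max_delta = 0.0
    for m, p, t_i in winners:
        s = p // sec_len
        for i in range(cfg.win_len):
            for j in range(cfg.n_bands):
                t_j = raster[p * cfg.stride + i, j]
                w = out[m, s, i, j]
                if t_j != SILENT and t_j < t_i:
                    dw = a_plus * w * (1 - w)
                else:
                    dw = -a_minus * w * (1 - w)
                out[m, s, i, j] = w + dw
                max_delta = max(max_delta, abs(dw))
    return out, max_delta


def naive_winner_selection(fired_at, fire_potential, radius):
    """Repeated full scans for the best eligible spike, applying blocks."""
    n_maps, P = fired_at.shape
    pos_blocked = set()
    map_pos_blocked = set()
    taken = set()
    winners = []
    while True:
        candidates = []
        for m in range(n_maps):
            for p in range(P):
                if fired_at[m, p] == SILENT or (m, p) in taken:
                    continue
                if p in pos_blocked or (m, p) in map_pos_blocked:
                    continue
                candidates.append(
                    (fired_at[m, p], -fire_potential[m, p], m, p)
                )
        if not candidates:
            return winners
        t, negpot, m, p = min(candidates)
        winners.append((m, p, int(t)))
        taken.add((m, p))
        pos_blocked.add(p)
        for q in range(max(0, p - radius), min(P, p + radius + 1)):
            map_pos_blocked.add((m, q))


def naive_tempotron_potential(weights_k, latencies, t, tau_m, tau_s, v0):
    """Direct kernel sum for one class neuron at one time point."""
    total = 0.0
    for w, t_i in zip(weights_k, latencies):
        if t_i == SILENT or t < t_i:
            continue
        dt = t - t_i
        total += w * v0 * (np.exp(-dt / tau_m) - np.exp(-dt / tau_s))
    return total
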