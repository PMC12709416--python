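"""Independent brute-force oracles used by the tests.

Pure-numpy double-loop implementations written directly from the model
definitions; deliberately share no code with the production kernels.
"""

import numpy as np

K_BOND = 8368.0
L_BOND = 0.38
EPS = 0.8368
F_COULOMB = 138.935458


def min_image(d, box):
    return d - box * np.rint(d / box)


def brute_force_energies(pos, box, sigma, lam, charge, chain_index,
                         rc_lj=2.0, rc_elec=4.0, ldebye=1.0, dielectric=80.0):
    """(bonded, ashbaugh_hatch, electrostatic) by explicit double loop."""
    n = len(pos)
    e_bond = e_ah = e_dh = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = min_image(pos[i] - pos[j], box)
            r = float(np.sqrt((d**2).sum()))
            if j == i + 1 and chain_index[i] == chain_index[j]:
                e_bond += 0.5 * K_BOND * (r - L_BOND) ** 2
                continue
            s = 0.5 * (sigma[i] + sigma[j])
            l = 0.5 * (lam[i] + lam[j])
            if r <= rc_lj:
                ulj = 4 * EPS * ((s / r) ** 12 - (s / r) ** 6)
                if r <= 2 ** (1 / 6) * s:
                    e_ah += ulj + EPS * (1 - l)
                else:
                    e_ah += l * ulj
            qq = charge[i] * charge[j]
            if qq != 0.0 and r <= rc_elec:
                e_dh += F_COULOMB * qq / (dielectric * r) * np.exp(-r / ldebye)
    return e_bond, e_ah, e_dh


def brute_contact_map(traj_positions, box, slices_a, slices_b, cutoff):
    """Mean contact matrix over frames and chain pairs, explicit loops.

    ``cutoff`` may be a scalar or an (nA, nB) matrix of pair cutoffs.
    """
    n_a = slices_a[0].stop - slices_a[0].start
    n_b = slices_b[0].stop - slices_b[0].start
    acc = np.zeros((n_a, n_b))
    count = 0
    for pos in traj_positions:
        for sa in slices_a:
            for sb in slices_b:
                if sa == sb:
                    continue
                count += 1
                for i in range(n_a):
                    for j in range(n_b):
                        d = min_image(pos[sa.start + i] - pos[sb.start + j], box)
                        r = np.sqrt((d**2).sum())
                        c = cutoff if np.isscalar(cutoff) else cutoff[i, j]
                        acc[i, j] += r < c
    return acc / count
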