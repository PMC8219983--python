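"""Turner 2004 nearest-neighbor free-energy parameters (kcal/mol, 37 C).

The published parameter set distributed with the Vienna RNA package;
stacking terms are stored in their telescoped form (helix terminal
penalties absorbed into the stack/hairpin terms), so summing stacks plus
the hairpin closure term reproduces the full Turner energy of a perfect
hairpin. Base encoding: A=0, C=1, G=2, U=3. Pair encoding: CG=0, GC=1,
GU=2, UG=3, AU=4, UA=5.
"""

PAIR_NAMES = ['CG', 'GC', 'GU', 'UG', 'AU', 'UA']

# STACK[outer_pair][inner_pair]
STACK = [[-3.3, -2.4, -1.9, -2.6, -2.6, -2.6], [-3.4, -3.3, -2.0, -3.0, -2.9, -2.7], [-2.0, -1.6, -0.5, 1.3, -1.3, -1.4], [-1.0, -0.9, 0.3, -0.5, -1.0, -0.6], [-1.7, -1.6, -0.6, -1.4, -0.9, -1.1], [-1.9, -1.6, -1.0, -1.3, -1.3, -0.9]]

# Hairpin-loop initiation by loop size (3..30); beyond 30 extrapolate
# init(30) + LXC * ln(n/30).
HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4, 10: 6.5, 11: 6.6, 12: 6.7, 13: 6.8, 14: 6.9, 15: 6.9, 16: 7.0, 17: 7.1, 18: 7.1, 19: 7.2, 20: 7.2, 21: 7.3, 22: 7.3, 23: 7.4, 24: 7.4, 25: 7.5, 26: 7.5, 27: 7.5, 28: 7.6, 29: 7.6, 30: 7.7}

LXC = 1.079

# Terminal mismatch of hairpin loops (loop size >= 4):
# MISMATCH_HAIRPIN[pair][first_loop_base][last_loop_base]
MISMATCH_HAIRPIN = {'CG': [[-1.5, -1.5, -1.4, -1.5], [-1.0, -1.1, -1.0, -0.8], [-2.3, -1.5, -2.4, -1.5], [-1.0, -1.4, -1.0, -2.1]], 'GC': [[-1.1, -1.5, -1.3, -1.5], [-1.1, -0.7, -1.1, -0.5], [-2.5, -1.5, -2.2, -1.5], [-1.1, -1.0, -1.1, -1.6]], 'GU': [[0.7, 0.0, 0.2, 0.0], [0.4, 0.3, 0.4, 0.3], [-0.5, 0.0, -0.6, 0.0], [0.4, 0.2, 0.4, -0.5]], 'UG': [[0.0, 0.2, -0.1, 0.2], [0.3, 0.4, 0.3, 0.5], [-0.4, 0.2, -0.6, 0.2], [0.3, 0.4, 0.3, -0.4]], 'AU': [[0.2, 0.0, 0.2, 0.0], [0.4, 0.3, 0.4, 0.3], [-0.7, 0.0, -0.6, 0.0], [0.4, 0.2, 0.4, -0.7]], 'UA': [[0.0, 0.2, 0.0, 0.2], [0.3, 0.4, 0.3, 0.5], [-1.0, 0.2, -1.0, 0.2], [0.3, 0.4, 0.3, -0.4]]}

# Closure term for 3-nt loops (no mismatch stacking in triloops)
TRILOOP_CLOSE = {'CG': 0.0, 'GC': 0.0, 'GU': 1.0, 'UG': 1.0, 'AU': 1.0, 'UA': 1.0}

# Bulge-loop initiation by size; size 1 retains the flanking stack.
BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}

# Interior-loop initiation by total unpaired size, plus 0.6/nt asymmetry
# (capped at 3.0); a coarse fit to the Turner 2004 internal-loop tables.
INTERIOR_INIT = {2: 0.9, 3: 1.9, 4: 1.25, 5: 2.0, 6: 2.0}
INTERIOR_ASYM = 0.6
INTERIOR_ASYM_MAX = 3.0
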