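"""Single table of every constant used by the 30 VF-detection features.

Each feature is implemented from its published definition (reference given per
block).  Where the original description leaves a constant or statistic open
(count bin edges, the x1–x5 statistics of the narrow band-pass analysis, and
the bCP/bWT/bW measures), the values below are this package's documented
convention; swap points are the module-level functions, not hidden literals.
"""

# ---- threshold crossing interval (TCI; Thakor et al., 1990) ----
TCI_STAGE_S = 1.0          # analysis stage length
TCI_THRESHOLD = 0.2        # binary threshold, fraction of stage max |x|
TCI_CAP_MS = 1000.0        # value when a stage contains no pulse

# ---- threshold crossing sample count (TCSC; Arafat et al., 2009) ----
TCSC_WIN_S = 3.0           # sub-window length
TCSC_HOP_S = 1.0           # sub-window hop
TCSC_TAPER_S = 0.25        # cosine taper ramp at each sub-window edge
TCSC_THRESHOLD = 0.2       # relative threshold after max-normalization

# ---- standard / modified exponential (Exp, Expmod; cf. Amann et al., 2005) ----
EXP_TAU_S = 3.0            # decay constant of the global envelope
EXPMOD_TAU_S = 0.2         # decay constant of the resetting envelope

# ---- mean absolute value (MAV; Anas et al., 2010) ----
MAV_WIN_S = 2.0            # non-overlapping sub-window length

# ---- count1-3 amplitude bins (after Jekova & Krasteva, 2004) ----
COUNT_MA_S = 0.04          # moving-average smoothing of |x|, seconds
COUNT1_LO = 0.5            # count1: aux >= 0.5 * max(aux)
COUNT3_HI = 0.2            # count3: aux <= 0.2 * max(aux)
# count2: aux >= mean(aux)

# ---- narrow band-pass analysis (x1-x5; after Jekova, 2000) ----
BP_LOW_HZ = 13.0
BP_HIGH_HZ = 16.5
BP_ORDER = 2               # Butterworth band-pass order, applied zero-phase
X4_BAND = (6.5, 13.0)      # relative power bands on the amplitude-squared
X5_BAND = (16.5, 30.0)     # spectrum; x3 uses (BP_LOW_HZ, BP_HIGH_HZ)
POWER_TOTAL_BAND = (0.5, 30.0)

# ---- slope-domain bCP ----
BCP_THRESHOLD = 0.5        # fraction of max |slope| defining a slope peak

# ---- VF-filter leakage (vFleak; Kuo & Dillman, 1978) ----
# no free constants: the comb lag is the estimated half mean period

# ---- spectral moment and band ratios (M, A1-A3; Barro et al., 1989) ----
PEAK_SEARCH_HZ = (0.5, 9.0)   # dominant-peak search band
SPECTRUM_CAP_FACTOR = 20.0    # analysis band cap: min(20*F, 30 Hz)
SPECTRUM_CAP_HZ = 30.0
A2_BAND_FACTORS = (0.7, 1.4)  # band around the dominant peak
A3_HARMONICS = range(2, 9)    # harmonic bands k*F +/- A3_HALF_WIDTH*F
A3_HALF_WIDTH = 0.3

# ---- wavelet band-energy features (Li, bWT, bW) ----
DWT_LEVELS = 6             # at 250 Hz: d5+d6 cover ~2-7.8 Hz (VF band),
LI_DETAIL_LEVELS = (5, 6)  # a6 covers < ~2 Hz (baseline), d1-d3 > ~15.6 Hz
BW_DETAIL_LEVELS = (1, 2, 3)

# ---- binary-signal features (CVbin, abin, Frqbin; after Ayala et al.) ----
BIN_THRESHOLD = 0.2        # binary: |x| >= 0.2 * max |x|
CVBIN_WIN_S = 1.0          # sub-window for the area coefficient of variation

# ---- phase-space reconstruction / Hilbert occupancy (Amann et al., 2007) ----
PSR_DELAY_S = 0.5
GRID_BINS = 40             # 40x40 occupancy grid

# ---- sample entropy (Richman & Moorman, 2000) ----
SAMPEN_M = 2
SAMPEN_R = 0.2             # tolerance, fraction of the segment SD
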