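# Landmarks of one rDNA repeat unit on sacCer3 chromosome XII.
# All coordinates are 1-based inclusive (genome-browser convention).
#
# The rARS sits at base pair 458,991; the c-pro non-coding transcript
# initiates 200 bp upstream and reads rightward through the origin.  The
# Reb1 binding site lies immediately upstream of c-pro and serves as the
# internal normalization site for occupancy comparisons.  The analysis
# window is the 1.25 kb region spanning the origin; the downstream window
# (rars .. downstream_end) receives transcription-displaced pre-RC signal
# and its 400 bp extent is a tunable, not a measured value.
chrom: chrXII
repeat_start: 451576
repeat_end: 460675
reb1_start: 458741
reb1_end: 458765
c_pro_start: 458791
rars: 458991
five_s_start: 459601
five_s_end: 459720
window_start: 458700
window_end: 459949
downstream_end: 459390
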