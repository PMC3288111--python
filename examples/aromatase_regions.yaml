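# Region definitions for human placental aromatase (CYP19A1, PDB entry 3EQM).
#
# heme / substrate are selected by hetero residue name; all other regions by
# residue number.  The access-channel, E-site and P-site lists are the
# published ones.  The catalytic cleft is intentionally left empty so the
# 4.5-A substrate-proximity fallback defines it; the proximal-cavity list is
# a declared approximation assembled from the named K''-L-loop and
# heme-coordinating residues plus the electropositive proximal-surface
# residues, and should be overridden if a curated list is available.
heme: [HEM]
substrate: [ASD]
catalytic_cleft: []
access_channel: [192, 217, 218, 221, 222, 225, 308, 309, 310, 312, 313,
                 369, 474, 478, 479, 480, 481, 482, 483, 484]
proximal_cavity: [142, 145, 352, 354, 355, 375, 417, 418, 419, 420, 421,
                  422, 423, 424, 425, 426, 427, 428, 429, 430, 431, 432,
                  433, 434, 435, 436, 437, 438, 439, 440, 448]
e_site: [177, 186, 197, 209, 210, 222, 482, 483, 489]
p_site: [142, 145, 352, 375, 440, 448, HEM]
layer_radii: [15.0, 20.0]
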