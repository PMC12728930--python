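# CHI torsional penalty profiles for glycosidic/aglycone linkages,
# expressed as truncated cosine series in the phi dihedral (degrees):
#
#   E(phi) = scale * sum_k [ a_k * cos(k * phi) ]     (k = 0, 1, 2, 3)
#
# Profiles are periodic in 360 degrees by construction and are meant to
# encode the exo-anomeric preference of the anomeric phi angle for
# gauche rotamers (|phi| near 60 deg) over the trans rotamer (180 deg).
#
# The shipped anomeric profile E = 0.6*(1.5 - 2 cos phi + cos 2phi) has
# exact minima at phi = +/-60 deg (E = 0), a 2.7 kcal/mol penalty at
# trans and a 0.3 kcal/mol shoulder at syn. The alpha and beta variants
# default to the same symmetric profile; both are user-overridable.
# The generic profile is a mild 3-fold staggered preference used for
# non-anomeric linkage torsions.

anomeric:
  scale: 0.6
  coefficients: [1.5, -2.0, 1.0, 0.0]
anomeric_alpha:
  scale: 0.6
  coefficients: [1.5, -2.0, 1.0, 0.0]
anomeric_beta:
  scale: 0.6
  coefficients: [1.5, -2.0, 1.0, 0.0]
generic:
  scale: 0.25
  coefficients: [1.0, 0.0, 0.0, 1.0]
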