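# Literature-standard Raman band assignments for lignified plant cell walls.
# These are editable configuration, not code: centers in cm^-1, windowed-max
# intensity at center +/- half_window on the baseline-corrected spectrum.
#
#   cellulose_378   C-C-C ring deformation of crystalline/amorphous cellulose
#   cellulose_380   crystallinity-sensitive cellulose band (numerator)
#   cellulose_1096  glycosidic C-O-C stretch (crystallinity denominator)
#   lignin_1600     aromatic ring stretch, total lignin proxy
#   s_1331          syringyl-associated ring mode
#   g_1271          guaiacyl ring/C-O mode
#   gcho_1621       coniferaldehyde (terminal G_CHO) ring-conjugated C=C
#   gchoh_1654      coniferyl alcohol (G_CHOH) C=C stretch
bands:
  cellulose_378: {center: 378, half_window: 4}
  cellulose_380: {center: 380, half_window: 4}
  cellulose_1096: {center: 1096, half_window: 4}
  lignin_1600: {center: 1600, half_window: 4}
  s_1331: {center: 1331, half_window: 4}
  g_1271: {center: 1271, half_window: 4}
  gcho_1621: {center: 1621, half_window: 4}
  gchoh_1654: {center: 1654, half_window: 4}
ratios:
  lignin_over_cellulose: {num: [lignin_1600], den: [cellulose_378]}
  s_over_g: {num: [s_1331], den: [g_1271]}
  gcho_over_gchoh: {num: [gcho_1621], den: [gchoh_1654]}
  crystallinity: {num: [cellulose_380], den: [cellulose_1096]}
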