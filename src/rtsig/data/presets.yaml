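# Built-in reverse-transcription condition presets (EpiScript RT).
#
# One preset per reaction buffer: the Mg 3 mM standard buffer (reference) and
# four buffers replacing MgCl2 with MnCl2 at 0.5 / 1 / 3 / 5 mM. Probabilities
# are per synthesis event at one template position, conditional on the enzyme
# reaching that position.
#
# Anchored values (measured m1A averages under EpiScript):
#   * arrest probability 0.82 (Mg 3 mM) -> 0.24 (Mn 3 mM)
#   * misincorporation mass 0.54 (Mg 3 mM) -> 0.80 (Mn 3 mM)
# The modified-site effect peaks at 3 mM MnCl2 and falls off slightly at
# 5 mM; intermediate concentrations interpolate between the anchors.
#
# Everything else is a stylized choice, made once:
#   * Jump mass is small and delayed-dominant (incorporation at the modified
#     site followed by slippage over its 5' neighbour). Direct and double
#     jumps also remove the aligned base at the site and are therefore
#     conflated with arrest by the coverage-drop estimator (see
#     docs/methods.md, "estimator coupling"); keeping them rare keeps the
#     arrest feature interpretable. Totals: 0.02 (Mg) rising to ~0.10
#     (Mn 3 mM) for m1A.
#   * m22G responds less strongly than m1A; m1G and m3C show the same
#     qualitative pattern (arrest collapse, mismatch gain) as m1A.
#   * Background (non-modified sites): all event probabilities well below
#     0.1; misincorporation 1.0% (Mg) rising continuously with MnCl2 to
#     2.5% at 5 mM — background errors keep rising past the 3 mM peak of the
#     modified-site effect.
#   * prebase_bias 0.65 for m1A: misincorporated bases tend to mirror the 3'
#     neighbour the enzyme has just read (visible in worked-example profile
#     rows, where the dominant misincorporation tracks the prebase).
#   * read_length 75 (2 x 75 bp paired-end geometry); truncation keeps the
#     5'-most end of the cDNA, where the signature concentrates.
#   * paired_fraction 0.85: most molecules also yield a reverse mate over
#     the 3'-proximal window.

presets:
  EpiScript_Mg_3mM:
    label: EpiScript_Mg_3mM
    n_molecules_per_ref: 10000
    read_length: 75
    paired_fraction: 0.85
    background:
      p_arrest: 0.004
      p_jump_direct: 0.0006
      p_jump_delayed: 0.0006
      p_jump_double: 0.0003
      p_mismatch: 0.010
      n_fraction: 0.02
    per_mod:
      m1A:
        p_arrest: 0.82
        p_jump_direct: 0.002
        p_jump_delayed: 0.015
        p_jump_double: 0.003
        p_mismatch: 0.54
        n_fraction: 0.005
        prebase_bias: 0.65
      m22G:
        p_arrest: 0.70
        p_jump_direct: 0.002
        p_jump_delayed: 0.008
        p_jump_double: 0.002
        p_mismatch: 0.30
        n_fraction: 0.005
      m1G:
        p_arrest: 0.55
        p_jump_direct: 0.002
        p_jump_delayed: 0.008
        p_jump_double: 0.002
        p_mismatch: 0.35
        n_fraction: 0.005
      m3C:
        p_arrest: 0.60
        p_jump_direct: 0.002
        p_jump_delayed: 0.008
        p_jump_double: 0.002
        p_mismatch: 0.40
        n_fraction: 0.005

  EpiScript_Mn_0.5mM:
    label: EpiScript_Mn_0.5mM
    n_molecules_per_ref: 10000
    read_length: 75
    paired_fraction: 0.85
    background:
      p_arrest: 0.005
      p_jump_direct: 0.0008
      p_jump_delayed: 0.0008
      p_jump_double: 0.0004
      p_mismatch: 0.013
      n_fraction: 0.02
    per_mod:
      m1A:
        p_arrest: 0.68
        p_jump_direct: 0.002
        p_jump_delayed: 0.030
        p_jump_double: 0.004
        p_mismatch: 0.62
        n_fraction: 0.005
        prebase_bias: 0.65
      m22G:
        p_arrest: 0.62
        p_jump_direct: 0.002
        p_jump_delayed: 0.012
        p_jump_double: 0.002
        p_mismatch: 0.33
        n_fraction: 0.005
      m1G:
        p_arrest: 0.45
        p_jump_direct: 0.002
        p_jump_delayed: 0.012
        p_jump_double: 0.002
        p_mismatch: 0.42
        n_fraction: 0.005
      m3C:
        p_arrest: 0.50
        p_jump_direct: 0.002
        p_jump_delayed: 0.012
        p_jump_double: 0.002
        p_mismatch: 0.47
        n_fraction: 0.005

  EpiScript_Mn_1mM:
    label: EpiScript_Mn_1mM
    n_molecules_per_ref: 10000
    read_length: 75
    paired_fraction: 0.85
    background:
      p_arrest: 0.006
      p_jump_direct: 0.0009
      p_jump_delayed: 0.0011
      p_jump_double: 0.0005
      p_mismatch: 0.016
      n_fraction: 0.02
    per_mod:
      m1A:
        p_arrest: 0.50
        p_jump_direct: 0.003
        p_jump_delayed: 0.050
        p_jump_double: 0.004
        p_mismatch: 0.70
        n_fraction: 0.005
        prebase_bias: 0.65
      m22G:
        p_arrest: 0.54
        p_jump_direct: 0.002
        p_jump_delayed: 0.015
        p_jump_double: 0.003
        p_mismatch: 0.37
        n_fraction: 0.005
      m1G:
        p_arrest: 0.34
        p_jump_direct: 0.002
        p_jump_delayed: 0.015
        p_jump_double: 0.003
        p_mismatch: 0.50
        n_fraction: 0.005
      m3C:
        p_arrest: 0.38
        p_jump_direct: 0.002
        p_jump_delayed: 0.015
        p_jump_double: 0.003
        p_mismatch: 0.55
        n_fraction: 0.005

  EpiScript_Mn_3mM:
    label: EpiScript_Mn_3mM
    n_molecules_per_ref: 10000
    read_length: 75
    paired_fraction: 0.85
    background:
      p_arrest: 0.008
      p_jump_direct: 0.0012
      p_jump_delayed: 0.0015
      p_jump_double: 0.0006
      p_mismatch: 0.022
      n_fraction: 0.02
    per_mod:
      m1A:
        p_arrest: 0.24
        p_jump_direct: 0.003
        p_jump_delayed: 0.090
        p_jump_double: 0.005
        p_mismatch: 0.80
        n_fraction: 0.005
        prebase_bias: 0.65
      m22G:
        p_arrest: 0.45
        p_jump_direct: 0.002
        p_jump_delayed: 0.020
        p_jump_double: 0.003
        p_mismatch: 0.42
        n_fraction: 0.005
      m1G:
        p_arrest: 0.22
        p_jump_direct: 0.002
        p_jump_delayed: 0.020
        p_jump_double: 0.003
        p_mismatch: 0.60
        n_fraction: 0.005
      m3C:
        p_arrest: 0.25
        p_jump_direct: 0.002
        p_jump_delayed: 0.020
        p_jump_double: 0.003
        p_mismatch: 0.65
        n_fraction: 0.005

  EpiScript_Mn_5mM:
    label: EpiScript_Mn_5mM
    n_molecules_per_ref: 10000
    read_length: 75
    paired_fraction: 0.85
    background:
      p_arrest: 0.009
      p_jump_direct: 0.0014
      p_jump_delayed: 0.0018
      p_jump_double: 0.0007
      p_mismatch: 0.025
      n_fraction: 0.02
    per_mod:
      m1A:
        p_arrest: 0.30
        p_jump_direct: 0.003
        p_jump_delayed: 0.080
        p_jump_double: 0.005
        p_mismatch: 0.76
        n_fraction: 0.005
        prebase_bias: 0.65
      m22G:
        p_arrest: 0.48
        p_jump_direct: 0.002
        p_jump_delayed: 0.018
        p_jump_double: 0.003
        p_mismatch: 0.40
        n_fraction: 0.005
      m1G:
        p_arrest: 0.26
        p_jump_direct: 0.002
        p_jump_delayed: 0.018
        p_jump_double: 0.003
        p_mismatch: 0.57
        n_fraction: 0.005
      m3C:
        p_arrest: 0.29
        p_jump_direct: 0.002
        p_jump_delayed: 0.018
        p_jump_double: 0.003
        p_mismatch: 0.62
        n_fraction: 0.005
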