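# Lipid subclass registry.
#
# Element maps are *net* contributions to the species formula:
#   formula = backbone + headgroup + steryl residue (free form)
#             + sum of chain formulas (free acid / free base)
#             - one H2O per ester/amide-bound acyl chain
# Sphingoid bases are the backbone itself and lose no water; headgroup maps
# are stored already condensed (glycosidic/phosphodiester water removed).
# ionization_mode records the MRM polarity used for the subclass.

subclasses:
  # -- glycerophospholipids (diacyl) ------------------------------------
  PC:   {category: glycerophospholipid, n_chains: 2, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 5, H: 12, N: 1, O: 3, P: 1}, ionization_mode: positive}
  PE:   {category: glycerophospholipid, n_chains: 2, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 2, H: 6, N: 1, O: 3, P: 1}, ionization_mode: positive}
  PA:   {category: glycerophospholipid, n_chains: 2, backbone: {C: 3, H: 8, O: 3}, headgroup: {H: 1, O: 3, P: 1}, ionization_mode: negative}
  PI:   {category: glycerophospholipid, n_chains: 2, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 6, H: 11, O: 8, P: 1}, ionization_mode: negative}
  PS:   {category: glycerophospholipid, n_chains: 2, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 3, H: 6, N: 1, O: 5, P: 1}, ionization_mode: negative}
  PG:   {category: glycerophospholipid, n_chains: 2, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 3, H: 7, O: 5, P: 1}, ionization_mode: negative}

  # -- galactoglycerolipids ---------------------------------------------
  MGDG: {category: galactoglycerolipid, n_chains: 2, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 6, H: 10, O: 5}, ionization_mode: positive}
  DGDG: {category: galactoglycerolipid, n_chains: 2, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 12, H: 20, O: 10}, ionization_mode: positive}

  # -- neutral glycerolipids --------------------------------------------
  DG:   {category: neutral glycerolipid, n_chains: 2, backbone: {C: 3, H: 8, O: 3}, headgroup: {}, ionization_mode: positive}
  TG:   {category: neutral glycerolipid, n_chains: 3, backbone: {C: 3, H: 8, O: 3}, headgroup: {}, ionization_mode: positive}

  # -- lyso (monoacyl) glycerophospholipids / galactolipids -------------
  LPC:  {category: lyso-glycerophospholipid, n_chains: 1, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 5, H: 12, N: 1, O: 3, P: 1}, ionization_mode: positive}
  LPE:  {category: lyso-glycerophospholipid, n_chains: 1, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 2, H: 6, N: 1, O: 3, P: 1}, ionization_mode: positive}
  LPA:  {category: lyso-glycerophospholipid, n_chains: 1, backbone: {C: 3, H: 8, O: 3}, headgroup: {H: 1, O: 3, P: 1}, ionization_mode: negative}
  LPI:  {category: lyso-glycerophospholipid, n_chains: 1, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 6, H: 11, O: 8, P: 1}, ionization_mode: negative}
  LPG:  {category: lyso-glycerophospholipid, n_chains: 1, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 3, H: 7, O: 5, P: 1}, ionization_mode: negative}
  LPS:  {category: lyso-glycerophospholipid, n_chains: 1, backbone: {C: 3, H: 8, O: 3}, headgroup: {C: 3, H: 6, N: 1, O: 5, P: 1}, ionization_mode: negative}

  # -- sphingolipids ----------------------------------------------------
  # n_chains counts the sphingoid base plus (if present) the N-acyl chain.
  SPB:     {category: sphingolipid, n_chains: 1, backbone: {}, headgroup: {}, ionization_mode: positive}
  SPBP:    {category: sphingolipid, n_chains: 1, backbone: {}, headgroup: {H: 1, O: 3, P: 1}, ionization_mode: positive}
  Cer:     {category: sphingolipid, n_chains: 2, backbone: {}, headgroup: {}, ionization_mode: positive}
  CerP:    {category: sphingolipid, n_chains: 2, backbone: {}, headgroup: {H: 1, O: 3, P: 1}, ionization_mode: positive}
  HexCer:  {category: sphingolipid, n_chains: 2, backbone: {}, headgroup: {C: 6, H: 10, O: 5}, ionization_mode: positive}
  IPC:     {category: sphingolipid, n_chains: 2, backbone: {}, headgroup: {C: 6, H: 11, O: 8, P: 1}, ionization_mode: negative}
  GlcA-IPC:            {category: sphingolipid, n_chains: 2, backbone: {}, headgroup: {C: 12, H: 19, O: 14, P: 1}, ionization_mode: negative}
  HexNAc-GlcA-IPC:     {category: sphingolipid, n_chains: 2, backbone: {}, headgroup: {C: 20, H: 32, N: 1, O: 19, P: 1}, ionization_mode: negative}
  Hex-HexNAc-GlcA-IPC: {category: sphingolipid, n_chains: 2, backbone: {}, headgroup: {C: 26, H: 42, N: 1, O: 24, P: 1}, ionization_mode: negative}

  # -- sterol lipids ----------------------------------------------------
  # n_chains counts acyl chains only; the steryl residue is named separately.
  FS:  {category: sterol_lipid, n_chains: 0, backbone: {}, headgroup: {}, ionization_mode: positive}
  SE:  {category: sterol_lipid, n_chains: 1, backbone: {}, headgroup: {}, ionization_mode: positive}
  SG:  {category: sterol_lipid, n_chains: 0, backbone: {}, headgroup: {C: 6, H: 10, O: 5}, ionization_mode: positive}
  ASG: {category: sterol_lipid, n_chains: 1, backbone: {}, headgroup: {C: 6, H: 10, O: 5}, ionization_mode: positive}

# Free-sterol formulas for the six mass-grouped steryl residues measured.
# M412 groups stigmasterol / putative methylenepollinastanol / isofucosterol /
# 24-methylenelophenol; M398 groups 24-methylenecholesterol / d5,24-ergostadienol.
steryl_residues:
  cholesterol:   {C: 27, H: 46, O: 1}
  campesterol:   {C: 28, H: 48, O: 1}
  sitosterol:    {C: 29, H: 50, O: 1}
  M412:          {C: 29, H: 48, O: 1}
  M398:          {C: 28, H: 46, O: 1}
  cycloeucalenol: {C: 30, H: 50, O: 1}
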