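angles:
  B1SP:A:
    k: 10.0
    theta0: 1.8741158794710877
  B1SP:C:
    k: 10.0
    theta0: 1.944174606603557
  B1SP:G:
    k: 10.0
    theta0: 1.8240531890222655
  B1SP:U:
    k: 10.0
    theta0: 1.9548642103273028
  PSB1:A:
    k: 10.0
    theta0: 2.2763456022938673
  PSB1:C:
    k: 10.0
    theta0: 1.9097598391995034
  PSB1:G:
    k: 10.0
    theta0: 2.346753876643208
  PSB1:U:
    k: 10.0
    theta0: 1.9019551225935594
  PSP:
    k: 10.0
    theta0: 2.071197474484882
  SB1B2:A:
    k: 10.0
    theta0: 0.4117532701105788
  SB1B2:C:
    k: 10.0
    theta0: 2.2871572048496622
  SB1B2:G:
    k: 10.0
    theta0: 0.48825608385161173
  SB1B2:U:
    k: 10.0
    theta0: 2.291325770333187
  SB1B3:A:
    k: 10.0
    theta0: 0.13776301289020348
  SB1B3:C:
    k: 10.0
    theta0: 1.2045079467669761
  SB1B3:G:
    k: 10.0
    theta0: 0.07826685174340627
  SB1B3:U:
    k: 10.0
    theta0: 1.2084221418603733
  SPS:
    k: 10.0
    theta0: 1.825542777928293
bonds:
  B1B2:A:
    b0: 3.493867307753983
    k: 20.0
  B1B2:C:
    b0: 2.835096483637659
    k: 20.0
  B1B2:G:
    b0: 3.7072888371887514
    k: 20.0
  B1B2:U:
    b0: 2.838084534610088
    k: 20.0
  B2B3:A:
    b0: 2.0309870804026455
    k: 20.0
  B2B3:C:
    b0: 2.694483633591092
    k: 20.0
  B2B3:G:
    b0: 2.0315978041837077
    k: 20.0
  B2B3:U:
    b0: 2.693760698408088
    k: 20.0
  B3B1:A:
    b0: 2.0803231628067267
    k: 20.0
  B3B1:C:
    b0: 2.1947652191987963
    k: 20.0
  B3B1:G:
    b0: 2.0097671821745076
    k: 20.0
  B3B1:U:
    b0: 2.1975383063930027
    k: 20.0
  PS:
    b0: 3.8311420374674787
    k: 20.0
  SB1:A:
    b0: 7.321762818034151
    k: 20.0
  SB1:C:
    b0: 4.297150225249798
    k: 20.0
  SB1:G:
    b0: 7.262357188165142
    k: 20.0
  SB1:U:
    b0: 4.292899480689751
    k: 20.0
  SP:
    b0: 3.9680758393731073
    k: 20.0
excluded_volume:
  eps: 1.0
  r_ev: 3.5
pairing:
  WC:
    eps: 4.0
    r0: 3.7248512368209976
    sigma: 1.0
  noncanonical:
    eps: 2.0
    r0: 3.7248512368209976
    sigma: 1.0
  wobble:
    eps: 2.5
    r0: 3.7248512368209976
    sigma: 1.0
torsions:
  CHI:A:
    k: 1.0
    n: 1
    phi0: -0.6073026715948078
  CHI:C:
    k: 1.0
    n: 1
    phi0: 2.0567386161330172
  CHI:G:
    k: 1.0
    n: 1
    phi0: -0.6403711016296266
  CHI:U:
    k: 1.0
    n: 1
    phi0: 2.0914311416083287
  PSPS:
    k: 1.0
    n: 1
    phi0: 2.8481410339338
  SPSP:
    k: 1.0
    n: 1
    phi0: 2.9685614794024255
version: 1
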