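# Pool library for the multi-pool brain model at 9.4 T.
#
# These are editable working defaults assembled from the CEST literature
# (amine/guanidinium exchange rates, NOE and semisolid MT pool sizes typical
# of mouse brain); they are configuration, not measured ground truth.
# fraction: proton fraction relative to water (= 1).
# k_exch:   solute -> water exchange rate, s^-1 (reverse rate = fraction * k_exch).
# t1, t2:   relaxation times, s.  All pools use a Lorentzian lineshape.
pools:
  - name: water
    delta_ppm: 0.0
    fraction: 1.0
    k_exch: 0.0
    t1: 2.0
    t2: 0.05
  - name: glutamate_amine        # fast-exchanging amine protons, 3.0 ppm
    delta_ppm: 3.0
    fraction: 0.0003
    k_exch: 5500.0
    t1: 1.0
    t2: 0.01
  - name: pcr_guanidinium        # phosphocreatine guanidinium, 2.64 ppm
    delta_ppm: 2.64
    fraction: 0.00015
    k_exch: 140.0
    t1: 1.0
    t2: 0.015
  - name: cr_guanidinium         # creatine guanidinium, 2.0 ppm
    delta_ppm: 2.0
    fraction: 0.00025
    k_exch: 810.0
    t1: 1.0
    t2: 0.015
  - name: amide                  # backbone amide protons, 3.5 ppm
    delta_ppm: 3.5
    fraction: 0.0007
    k_exch: 30.0
    t1: 1.0
    t2: 0.01
  - name: noe_m3p5               # relayed NOE, -3.5 ppm
    delta_ppm: -3.5
    fraction: 0.005
    k_exch: 20.0
    t1: 1.0
    t2: 0.001
  - name: noe_m1p6               # relayed NOE, -1.6 ppm
    delta_ppm: -1.6
    fraction: 0.002
    k_exch: 20.0
    t1: 1.0
    t2: 0.001
  - name: mt_symmetric           # semisolid MT centred on water
    delta_ppm: 0.0
    fraction: 0.07
    k_exch: 25.0
    t1: 1.0
    t2: 9.1e-6
  - name: mt_asymmetric          # semisolid MT centred at -2.3 ppm
    delta_ppm: -2.3
    fraction: 0.07
    k_exch: 25.0
    t1: 1.0
    t2: 9.1e-6
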