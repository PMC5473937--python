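wavelength_nm,eps_real,eps_imag
381.49,-1.6049,5.6444
397.39,-1.6494,5.7389
413.28,-1.7022,5.7174
430.50,-1.6922,5.6492
450.85,-1.7590,5.2826
471.42,-1.7027,4.8444
495.94,-2.2783,3.8126
520.94,-3.9462,2.5804
548.60,-5.8421,2.1113
582.09,-8.1127,1.6605
616.84,-10.6619,1.3742
659.49,-13.6482,1.0352
704.46,-16.8177,1.0668
756.00,-20.6102,1.2718
821.09,-25.8113,1.6266
891.97,-32.0407,1.9254
984.00,-40.2741,2.7940
1087.58,-51.0496,3.8610
1215.53,-66.2185,5.7015
1393.08,-90.4265,8.1863
1610.18,-125.3505,12.5552
1937.25,-189.0420,25.3552
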