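(Haematomyzus_elephantis,(Microthoracius_praelongiceps,(((Polyplax_asiatica,(Polyplax_spinulosa,Polyplax_reclinata)),(Hoplopleura_akanezumi,Hoplopleura_kitti)),((((Pediculus_schaeffi,(Pediculus_capitis,Pediculus_humanus)),Pthirus_pubis),(Pedicinus_obtusus,Pedicinus_badii)),(Haematopinus_asini,(Haematopinus_apri,Haematopinus_suis))))));
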