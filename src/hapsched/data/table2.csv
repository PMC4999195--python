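drug,dose,schedule,tolerated,n,location
erlotinib,25,daily for 3 days/week,yes,9,below
erlotinib,50,daily for 3 days/week,yes,9,below
erlotinib,50,daily,yes,21,below
erlotinib,100,daily for 3 days/week,yes,9,on/below
erlotinib,100,daily,yes,21,below
erlotinib,100,twice daily,no,42,above
erlotinib,150,daily,yes,21,on/below
erlotinib,200,daily,no,21,above
erlotinib,250,daily,no,21,above
erlotinib,1200,weekly,yes,3,below
erlotinib,1600,weekly,yes,3,below
erlotinib,2000,weekly,yes,3,on/below
evofosfamide,7.5,weekly,yes,3,below
evofosfamide,15,weekly,yes,3,below
evofosfamide,30,weekly,yes,3,below
evofosfamide,60,weekly,yes,3,below
evofosfamide,120,weekly,yes,3,below
evofosfamide,120,5 days every 3 weeks,yes,5,below
evofosfamide,170,5 days every 3 weeks,yes,5,below
evofosfamide,240,weekly,yes,3,below
evofosfamide,240,5 days every 3 weeks,yes,5,below
evofosfamide,330,5 days every 3 weeks,yes,5,below
evofosfamide,460,5 days every 3 weeks,yes,5,on/below
evofosfamide,480,weekly,yes,3,below
evofosfamide,550,5 days every 3 weeks,no,5,above
evofosfamide,575,weekly,yes,3,on/below
evofosfamide,670,weekly,no,3,above
evofosfamide,670,once every 3 weeks,yes,1,on/below
evofosfamide,940,once every 3 weeks,no,1,above
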