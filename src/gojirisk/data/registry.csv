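chem_id,display_name,chem_class,lod_mg_per_kg,mrl_mg_per_kg,mrl_source,adi_ug_per_kg_day,carcinogenic,slope_factor_per_mg_kg_day
dichlorvos,Dichlorvos,pesticide,0.0050,1.0,EU pesticide MRL,4,false,
omethoate,Omethoate,pesticide,0.0100,0.5,EU pesticide MRL,3,false,
malathion,Malathion,pesticide,0.0050,1.0,EU pesticide MRL,300,false,
cypermethrin,Cypermethrin,pesticide,0.0100,0.5,EU pesticide MRL,20,false,
fenvalerate,Fenvalerate,pesticide,0.0200,1.5,EU pesticide MRL,20,false,
deltamethrin,Deltamethrin,pesticide,0.0200,0.5,EU pesticide MRL,10,false,
Pb,Lead,metal,0.0024,5.0,China MRL for medicinal plants,3.6,false,
Cd,Cadmium,metal,0.0702,0.3,China MRL for medicinal plants,1,false,
Cu,Copper,metal,0.0093,20,China MRL for medicinal plants,40,false,
Ni,Nickel,metal,0.0034,0.2,China MRL for fruits,20,false,
Zn,Zinc,metal,0.0021,5.0,China MRL for fruits,300,false,
As,Arsenic,metal,0.0075,2.0,China MRL for medicinal plants,0.3,true,1.5
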