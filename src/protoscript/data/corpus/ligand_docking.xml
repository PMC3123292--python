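<ROSETTASCRIPTS>
	<SCOREFXNS>
		<ligand_soft_rep weights = ligand_soft_rep> use a soft potential from the database
			<Reweight scoretype = hack_elec weight = 0.42/> change the Coloumb electrostatic weight to 0.42
		</ligand_soft_rep>
		<hard_rep weights = ligand>
			<Reweight scoretype = hack_elec weight = 0.42/>
		</hard_rep>
	</SCOREFXNS>
	<LIGAND_AREAS>
		<docking_sidechain chain = X cutoff = 6.0 add_nbr_radius = true all_atom_mode = true minimize_ligand = 10/>
		<final_sidechain chain = X cutoff = 6.0 add_nbr_radius = true all_atom_mode = true/>
		<final_backbone chain = X cutoff = 7.0 add_nbr_radius = false all_atom_mode = true Calpha_restraints = 0.3/>
	</LIGAND_AREAS>
	<INTERFACE_BUILDERS>
		<side_chain_for_docking ligand_areas = docking_sidechain/>
		<side_chain_for_final ligand_areas = final_sidechain/>
		<backbone ligand_areas = final_backbone extension_window = 3/>
	</INTERFACE_BUILDERS>
	<MOVEMAP_BUILDERS>
		<docking sc_interface = side_chain_for_docking minimize_water = true/>
		<final sc_interface = side_chain_for_final bb_interface = backbone minimize_water = true/>
	</MOVEMAP_BUILDERS>
	<MOVERS>
		single movers
		<StartFrom name = start_from chain = X>
			<Coordinates x = -1.731 y = 32.589 z = -5.039/>
		</StartFrom>
		<Translate name = translate chain = X distribution = uniform angstroms = 0.01 cycles = 50/>
		<Rotate name = rotate chain = X distribution = uniform degrees = 360 cycles = 1000/>
		<SlideTogether name = slide_together chain = X/>
		<HighResDocker name = high_res_docker chains = X cycles = 6 repack_every_Nth = 3 scorefxn = ligand_soft_rep movemap_builder = docking/>
		<FinalMinimizer name = final scorefxn = hard_rep movemap_builder = final/>
		<InterfaceScoreCalculator name = add_scores chains = X scorefxn = hard_rep native="inputs/7cpa_7cpa_native.pdb"/>
		compound movers
		<ParsedProtocol name = low_res_dock>
			<Add mover_name = start_from/>
			<Add mover_name = translate/>
			<Add mover_name = rotate/>
			<Add mover_name = slide_together/>
		</ParsedProtocol>
		<ParsedProtocol name = high_res_dock>
			<Add mover_name = high_res_docker/>
			<Add mover_name = final/>
		</ParsedProtocol>
	</MOVERS>
	<PROTOCOLS>
		<Add mover_name = low_res_dock/>
		<Add mover_name = high_res_dock/>
		<Add mover_name = add_scores/>
	</PROTOCOLS>
</ROSETTASCRIPTS>
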